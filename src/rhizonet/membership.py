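"""Core-taxon, unique-taxon, and prevalence computations.

Presence means a raw count > 0; prevalence is therefore invariant to any
per-sample rescaling, and core membership computed on relative abundances
reduces to raw prevalence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountTable, TableError
from .diversity import NormalizedTable


def prevalence(ct: CountTable) -> pd.Series:
    """Fraction of samples with a positive count, per taxon."""
    if len(ct.sample_ids) == 0:
        raise TableError("prevalence requires at least one sample")
    frac = (ct.counts > 0).mean(axis=1)
    return pd.Series(frac, index=ct.taxon_ids, name="prevalence")


def core_taxa(nt: NormalizedTable | CountTable, threshold: float = 0.5) -> list[str]:
    """Taxa with prevalence >= threshold, sorted by descending prevalence
    then identifier."""
    values = nt.values if isinstance(nt, NormalizedTable) else nt.counts
    frac = (np.asarray(values) > 0).mean(axis=1)
    kept = [
        (tx, pv) for tx, pv in zip(nt.taxon_ids, frac) if pv >= threshold and pv > 0
    ]
    kept.sort(key=lambda item: (-item[1], item[0]))
    return [tx for tx, _ in kept]


def unique_taxa(
    ct: CountTable,
    md: pd.DataFrame,
    factor: str,
    baseline_level_of_time: str | None = None,
) -> dict[str, list[str]]:
    """Taxa present at exactly one level of a metadata factor.

    A taxon is unique to level L if it has a positive count in at least one
    sample of L and in no sample of any other level. For the treatment
    factor the baseline growth stage can be excluded first
    (``baseline_level_of_time``): uniqueness is assessed on the remaining
    samples, and taxa that were already present at baseline are removed, so
    a "treatment-unique" taxon genuinely appeared after the intervention.
    """
    if factor not in md.columns:
        raise TableError(f"metadata has no factor {factor!r}")
    md = md.set_index("sample_id").loc[ct.sample_ids]
    levels = sorted(md[factor].unique())
    if len(levels) < 2:
        raise TableError(f"factor {factor!r} has fewer than two levels")

    baseline_present: set[str] = set()
    keep = np.ones(len(ct.sample_ids), dtype=bool)
    if baseline_level_of_time is not None:
        is_baseline = (md["growth_stage"] == baseline_level_of_time).to_numpy()
        if is_baseline.any():
            present = (ct.counts[:, is_baseline] > 0).any(axis=1)
            baseline_present = {t for t, p in zip(ct.taxon_ids, present) if p}
        keep = ~is_baseline

    counts = ct.counts[:, keep]
    labels = md[factor].to_numpy()[keep]
    present_by_level = {
        lev: (counts[:, labels == lev] > 0).any(axis=1) for lev in levels
    }
    out: dict[str, list[str]] = {}
    for lev in levels:
        others = np.zeros(len(ct.taxon_ids), dtype=bool)
        for other in levels:
            if other != lev:
                others |= present_by_level[other]
        uniq = present_by_level[lev] & ~others
        out[lev] = [
            t
            for t, u in zip(ct.taxon_ids, uniq)
            if u and t not in baseline_present
        ]
    return out
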