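"""Synthetic community, phenotype, and fixture-graph generation.

The generator emulates a 64-sample field study laid out as a 2 treatments x
2 cultivars x 4 growth stages factorial replicated across 4 field blocks,
with two taxon domains (genus-level eukaryotes, species-level prokaryotes).

Counts are drawn through a Gaussian copula with negative-binomial marginals:

1. a latent Gaussian vector per sample, with identity correlation except on
   explicitly planted taxon pairs, plus a shared per-block Gaussian offset;
2. each latent value is mapped through the standard normal CDF to a uniform;
3. the uniform is inverted through the NB CDF (mean ``nb_mean``, dispersion
   ``nb_dispersion``) to an integer count;
4. an independent Bernoulli mask zeroes counts so per-taxon prevalence hits
   ``prevalence_target`` in expectation.

Because the copula preserves rank order, planted latent correlations
survive the monotone count transform as rank correlations, which is exactly
what the downstream Spearman inference estimates. The zero-inflation mask
is independent of the copula, so it attenuates (but does not bias the sign
of) planted associations.

Phenotypes are linear responses in log1p counts of designated taxa, plus a
block offset and Gaussian noise, so that lasso/GLM stages have a known
ground truth to recover.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTable, Network

TREATMENTS = ("control", "biostimulant")
CULTIVARS = ("CV_A", "CV_B")
GROWTH_STAGES = ("V1", "V6", "R2", "R6")

#: Lifestyle tags cycled deterministically over taxa, echoing the dominant
#: functional guilds of rhizosphere surveys.
_EUK_LIFESTYLES = ("saprotroph", "plant_pathogen", "mycorrhizal", "saprotroph")
_PROK_LIFESTYLES = ("diazotroph", "nitrifier", "saprotroph", "plant_growth_promoter")


class SimulationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic community.

    Defaults describe a desk-scale version of the field design: 64 samples
    in a 2x2x4 factorial over 4 blocks, a few dozen taxa per domain, and
    heavily overdispersed NB counts (dispersion 0.2 at mean 50) whose
    natural zero mass (~35%) supplies most of the sparsity. Because those
    zeros arise inside the copula they preserve planted rank structure;
    the independent Bernoulli mask only tops sparsity up to the target
    prevalence, so its rank-destroying attenuation stays small by default.
    """

    n_taxa_euk: int = 30
    n_taxa_prok: int = 30
    n_samples: int = 64
    nb_mean: float = 50.0
    nb_dispersion: float = 0.2
    prevalence_target: float = 0.65
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    planted_effects: list[tuple[str, str, float, float]] = field(default_factory=list)
    block_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise SimulationError("nb_mean and nb_dispersion must be positive")
        if not 0 < self.prevalence_target <= 1:
            raise SimulationError("prevalence_target must be in (0, 1]")
        if self.block_sd < 0:
            raise SimulationError("block_sd must be >= 0")
        for i, j, rho in self.planted_pairs:
            if i == j:
                raise SimulationError(f"planted pair references one taxon twice: {i!r}")
            if not abs(rho) < 1:
                raise SimulationError(f"planted correlation |{rho}| must be < 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["planted_pairs"] = [tuple(p) for p in raw.get("planted_pairs", [])]
        raw["planted_effects"] = [tuple(e) for e in raw.get("planted_effects", [])]
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Record of what was planted, for downstream recovery checks."""

    planted_pairs: list[tuple[str, str, float]]
    planted_effects: list[tuple[str, str, float, float]]
    prevalence: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def taxon_names(cfg: SimulationConfig) -> list[str]:
    width_e = max(2, len(str(cfg.n_taxa_euk)))
    width_p = max(2, len(str(cfg.n_taxa_prok)))
    euk = [f"Euk{g:0{width_e}d}" for g in range(1, cfg.n_taxa_euk + 1)]
    prok = [f"Prok{s:0{width_p}d}" for s in range(1, cfg.n_taxa_prok + 1)]
    return euk + prok


def factorial_metadata(n_samples: int) -> pd.DataFrame:
    """Balanced treatment x cultivar x stage x block metadata.

    Requires ``n_samples`` divisible by 16 (one sample per condition per
    block); the number of blocks is ``n_samples // 16``.
    """
    if n_samples % 16 != 0 or n_samples == 0:
        raise SimulationError(f"n_samples must be a positive multiple of 16, got {n_samples}")
    n_blocks = n_samples // 16
    rows = []
    k = 0
    for block in range(1, n_blocks + 1):
        for tr in TREATMENTS:
            for cv in CULTIVARS:
                for st in GROWTH_STAGES:
                    k += 1
                    rows.append(
                        {
                            "sample_id": f"S{k:03d}",
                            "treatment": tr,
                            "cultivar": cv,
                            "growth_stage": st,
                            "field_block": f"B{block}",
                        }
                    )
    return pd.DataFrame(rows)


def _correlation_matrix(taxa: list[str], pairs: list[tuple[str, str, float]]) -> np.ndarray:
    index = {t: i for i, t in enumerate(taxa)}
    for i, j, _ in pairs:
        for t in (i, j):
            if t not in index:
                raise SimulationError(f"planted pair references unknown taxon {t!r}")
    corr = np.eye(len(taxa))
    for i, j, rho in pairs:
        a, b = index[i], index[j]
        corr[a, b] = corr[b, a] = rho
    # eigencheck so a hard error names the offending structure
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() <= 1e-10:
        raise SimulationError(
            "planted correlation matrix is not positive definite; "
            f"offending pairs: {[(i, j) for i, j, _ in pairs]}"
        )
    return corr


def nb_zero_probability(mean: float, dispersion: float) -> float:
    """P(X = 0) for NB with the given mean and dispersion (size) k."""
    k = dispersion
    return float((k / (k + mean)) ** k)


def generate_community(
    cfg: SimulationConfig,
) -> tuple[CountTable, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw a synthetic count table with planted pairwise correlations.

    Returns ``(counts, metadata, annotations, truth)``; fully deterministic
    given ``cfg.seed``.
    """
    taxa = taxon_names(cfg)
    corr = _correlation_matrix(taxa, cfg.planted_pairs)
    md = factorial_metadata(cfg.n_samples)
    n, t = cfg.n_samples, len(taxa)

    ss = np.random.SeedSequence(cfg.seed)
    rng_latent, rng_block, rng_mask, _rng_ph = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    chol = np.linalg.cholesky(corr)
    latent = rng_latent.standard_normal((n, t)) @ chol.T
    blocks = md["field_block"].to_numpy()
    block_levels = sorted(set(blocks))
    offsets = rng_block.normal(0.0, cfg.block_sd, size=len(block_levels))
    offset_by_block = dict(zip(block_levels, offsets))
    latent += np.array([offset_by_block[b] for b in blocks])[:, None]

    u = stats.norm.cdf(latent)
    k = cfg.nb_dispersion
    p_nb = k / (k + cfg.nb_mean)
    counts = stats.nbinom.ppf(u, k, p_nb).astype(np.int64)

    # the block offset inflates the latent marginal to N(0, 1 + block_sd^2),
    # changing the NB's effective at-zero mass; account for it so the mask
    # hits the prevalence target in expectation over block draws
    p0 = nb_zero_probability(cfg.nb_mean, cfg.nb_dispersion)
    p0_eff = float(
        stats.norm.cdf(stats.norm.ppf(p0) / math.sqrt(1.0 + cfg.block_sd**2))
    )
    keep_prob = min(1.0, cfg.prevalence_target / (1.0 - p0_eff)) if p0_eff < 1 else 1.0
    if keep_prob < 1.0:
        mask = rng_mask.random((n, t)) < keep_prob
        counts = counts * mask

    ct = CountTable(taxa, list(md["sample_id"]), counts.T)
    ann = _annotations(cfg, taxa)
    prevalence = {
        tx: float((ct.counts[i] > 0).mean()) for i, tx in enumerate(taxa)
    }
    truth = SyntheticTruth(
        planted_pairs=list(cfg.planted_pairs),
        planted_effects=list(cfg.planted_effects),
        prevalence=prevalence,
        seed=cfg.seed,
    )
    return ct, md, ann, truth


def _annotations(cfg: SimulationConfig, taxa: list[str]) -> pd.DataFrame:
    rows = []
    for i, tx in enumerate(taxa):
        euk = i < cfg.n_taxa_euk
        life = _EUK_LIFESTYLES if euk else _PROK_LIFESTYLES
        rows.append(
            {
                "taxon_id": tx,
                "domain": "eukaryote" if euk else "prokaryote",
                "lineage": ("Fungi;" if euk else "Bacteria;") + tx,
                "lifestyle": life[i % len(life)],
            }
        )
    return pd.DataFrame(rows)


def generate_phenotypes(
    ct: CountTable,
    cfg: SimulationConfig,
    md: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate phenotype panels with planted taxon effects.

    Each phenotype named in ``cfg.planted_effects`` is the sum of
    ``effect_size * log1p(count)`` over its planted taxa, a per-block offset
    (sd ``cfg.block_sd``; zero when no metadata is supplied), and Gaussian
    noise with the per-effect ``noise_sd``.
    """
    for _, taxon, _, _ in cfg.planted_effects:
        if taxon not in ct.taxon_ids:
            raise SimulationError(f"planted effect references unknown taxon {taxon!r}")

    ss = np.random.SeedSequence(cfg.seed)
    _a, _b, _c, rng = [np.random.default_rng(s) for s in ss.spawn(4)]

    n = len(ct.sample_ids)
    by_phen: dict[str, list[tuple[str, float, float]]] = {}
    for name, taxon, eff, noise_sd in cfg.planted_effects:
        by_phen.setdefault(name, []).append((taxon, eff, noise_sd))

    block_offsets = np.zeros(n)
    data: dict[str, np.ndarray] = {}
    for name, effects in by_phen.items():
        if md is not None:
            blocks = (
                md.set_index("sample_id").loc[ct.sample_ids, "field_block"].to_numpy()
            )
            levels = sorted(set(blocks))
            offs = rng.normal(0.0, cfg.block_sd, size=len(levels))
            block_offsets = np.array([offs[levels.index(b)] for b in blocks])
        values = block_offsets.astype(float).copy()
        noise = max(sd for _, _, sd in effects)
        for taxon, eff, _ in effects:
            counts = ct.counts[ct.taxon_ids.index(taxon)].astype(float)
            values += eff * np.log1p(counts)
        if noise > 0:
            values += rng.normal(0.0, noise, size=n)
        data[name] = values

    ph = pd.DataFrame({"sample_id": ct.sample_ids, **data})
    truth = SyntheticTruth(
        planted_pairs=list(cfg.planted_pairs),
        planted_effects=list(cfg.planted_effects),
        prevalence={},
        seed=cfg.seed,
    )
    return ph, truth


def hub_scenario_config(seed: int = 0, n_taxa_euk: int = 15, n_taxa_prok: int = 15) -> SimulationConfig:
    """A community with one planted keystone taxon.

    The first eukaryote genus is strongly correlated (latent 0.85) with two
    tight blocks of three taxa each (within-block 0.9) — one eukaryotic,
    one prokaryotic — so it bridges the blocks topologically. Positive
    definiteness forces a floor on the cross-block correlation (two
    variables each at rho with a common hub require at least 2*rho^2 - 1 =
    0.445); it is set to 0.55, whose rank correlation on counts falls well
    below the 0.6 edge threshold, so cross-block edges stay out of the
    inferred network and the keystone's bridging role is preserved. The
    keystone additionally drives a phenotype (effect 2.0 per log-count
    unit, noise sd 0.5). Downstream inference should place it at the top
    of the prioritization report.
    """
    hub = "Euk01"
    block_a = ["Euk02", "Euk03", "Euk04"]
    block_b = ["Prok01", "Prok02", "Prok03"]
    pairs = [(hub, t, 0.85) for t in block_a + block_b]
    for block in (block_a, block_b):
        for i, a in enumerate(block):
            for b in block[i + 1 :]:
                pairs.append((a, b, 0.9))
    for a in block_a:
        for b in block_b:
            pairs.append((a, b, 0.55))
    return SimulationConfig(
        n_taxa_euk=n_taxa_euk,
        n_taxa_prok=n_taxa_prok,
        planted_pairs=pairs,
        planted_effects=[("soil_enzyme", hub, 2.0, 0.5)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fixture graphs
# ---------------------------------------------------------------------------

_FIXTURES = ("two_triangles", "three_triangles", "complete4", "star4", "path_n")


def fixture_graph(name: str) -> Network:
    """Small forced-structure networks used as topology fixtures.

    Recognized names: ``two_triangles`` (6 nodes / 6 edges / 2 components),
    ``three_triangles`` (9/9/3), ``complete4`` (K4), ``star4`` (one center,
    3 leaves), and ``path_<n>`` (a path on n nodes). Edges are unweighted
    positive associations.
    """
    edges: list[tuple[str, str]]
    m = re.fullmatch(r"path_(\d+)", name)
    if name == "two_triangles":
        edges = _triangles(2)
    elif name == "three_triangles":
        edges = _triangles(3)
    elif name == "complete4":
        nodes = [f"n{i}" for i in range(1, 5)]
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
    elif name == "star4":
        edges = [("n1", f"n{i}") for i in range(2, 5)]
    elif m:
        n = int(m.group(1))
        if n < 2:
            raise SimulationError("path_n requires n >= 2")
        edges = [(f"n{i}", f"n{i+1}") for i in range(1, n)]
    else:
        raise SimulationError(f"unknown fixture {name!r}; options: {_FIXTURES}")
    return Network.from_edges((u, v, 1.0, 0.0, 0.0) for u, v in edges)


def _triangles(k: int) -> list[tuple[str, str]]:
    edges = []
    for t in range(k):
        a, b, c = (f"n{3 * t + i}" for i in (1, 2, 3))
        edges += [(a, b), (b, c), (a, c)]
    return edges
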