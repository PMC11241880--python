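"""Published condition-specific network topology summaries.

Ten-metric topology summaries for the 16 condition-specific (growth stage x
treatment x cultivar) co-occurrence networks of a soybean rhizosphere field
study, one table per association method (Spearman, Pearson). They serve as
reference fixtures: several of the sparsest Spearman networks are uniquely
forced by their printed counts (e.g. the 6-node / 6-edge / 2-component /
giant-3 entry can only be two disjoint triangles), so the topology suite
can be checked against them exactly, and the row identities connectance =
2E/(N(N-1)) and mean degree = 2E/N hold against every printed row.

Condition codes: growth stage (V1, V6, R2, R6) - treatment (Ctrl = control,
Bst = biostimulant) - cultivar (79X, 10X).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Forced graph structures implied by degenerate printed rows: every node
#: has degree 2 (or 3 for K4), components and sizes pin down the graph.
FORCED_GRAPHS = {
    "V1-Ctrl-79X": "two_triangles",
    "V6-Ctrl-79X": "two_triangles",
    "V1-Bst-10X": "two_triangles",
    "V1-Ctrl-10X": "three_triangles",
    "V6-Ctrl-10X": "complete4",
}


def load_topologies(method: str = "spearman") -> pd.DataFrame:
    """Load the published topology table for one association method."""
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    ref = resources.files("rhizonet.data") / f"{method}_topologies.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"]).set_index("network")
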