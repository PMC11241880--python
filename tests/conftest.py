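import itertools

import numpy as np
import pandas as pd
import pytest

import rhizonet as rz


@pytest.fixture
def small_counts() -> rz.CountTable:
    counts = np.array(
        [
            [5, 0, 2, 7],
            [1, 3, 0, 2],
            [0, 0, 4, 1],
        ]
    )
    return rz.CountTable(["taxA", "taxB", "taxC"], ["s1", "s2", "s3", "s4"], counts)


@pytest.fixture
def factorial_dataset():
    """A default synthetic community with no planted structure."""
    cfg = rz.SimulationConfig(seed=11)
    ct, md, ann, truth = rz.generate_community(cfg)
    return cfg, ct, md, ann, truth


def all_partitions(nodes):
    """Every set partition of a node list (for exhaustive modularity search)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for part in all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_partition_modularity(net: rz.Network) -> float:
    """Brute-force maximum Newman-Girvan modularity over all partitions."""
    best = -2.0
    for part in all_partitions(sorted(net.graph.nodes)):
        labels = {v: i for i, block in enumerate(part) for v in block}
        best = max(best, rz.modularity(net, labels))
    return best


def spearman_bruteforce(values: np.ndarray) -> np.ndarray:
    """Double-loop Spearman correlation matrix via scipy, as an oracle."""
    from scipy import stats

    t = values.shape[0]
    out = np.eye(t)
    for i, j in itertools.combinations(range(t), 2):
        rho = stats.spearmanr(values[i], values[j]).statistic
        out[i, j] = out[j, i] = rho
    return out


def run_hub_pipeline(seed: int):
    """Network -> phenotype network -> prioritization on the hub scenario."""
    cfg = rz.hub_scenario_config(seed=seed)
    ct, md, _, _ = rz.generate_community(cfg)
    ph, _ = rz.generate_phenotypes(ct, cfg, md)
    ct = ct.drop_empty_samples()
    nt = rz.css_normalize(ct)
    net = rz.build_network(rz.pairwise_associations(nt))
    X = pd.DataFrame(nt.values.T, index=nt.sample_ids, columns=nt.taxon_ids)
    y = ph.set_index("sample_id").loc[nt.sample_ids, "soil_enzyme"].to_numpy()
    selected = rz.lasso_select(X, y, seed=seed)
    if selected.empty:
        glm = pd.DataFrame(columns=["taxon_id", "coefficient", "sign", "p"])
    else:
        glm = rz.fit_glm(
            X[selected["taxon_id"]], y, selected.set_index("taxon_id")["coefficient"]
        )
    prev = rz.prevalence(ct)
    pt = rz.assemble_phona(net, glm, "soil_enzyme", prev)
    report = rz.prioritize({"soil_enzyme": rz.score_network(pt)}, prev)
    return net, report
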