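"""Illustrative (synthetic) network-demo inputs.

The curated interaction list shipped under ``data/curated_edges_synthetic.sif``
is a hand-designed, SYNTHETIC stand-in for a curated-database edge set over
23 AD-related genes: it is hub-centered (APP connected to 17 of 22 other
genes, the remaining five at distance two) and contains 55 edges.  It is
illustrative plumbing for the network stage, not a real interaction
database export.

:func:`demo_network_inputs` pairs it with a deterministic two-group
expression matrix (5 cases per group) constructed so that exactly 22
non-curated gene pairs are perfectly rank-correlated within the control
group — the only way a pair can pass the |rho| >= 0.9 AND exact p < 0.05
novel-edge rule at n = 5 — while no other pair passes in either group.  The
union therefore has 77 edges, APP keeps the maximum degree (17), and its
closeness is 22/27.
"""

from __future__ import annotations

import itertools
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .network import read_sif

__all__ = [
    "DEMO_GENES",
    "PERFECT_CLUSTER",
    "curated_edges_path",
    "curated_edges",
    "demo_network_inputs",
]

DEMO_GENES = (
    "PSEN1", "MAPT", "APP", "NCSTN", "APOE", "ABCA1", "CLU", "A2M", "CTSC",
    "CTSD", "SERPINA3", "CASP4", "GNB2", "GNB1", "PRKCA", "PRKCZ", "PRKCG",
    "APBA1", "NTRK2", "HSD17B10", "UQCRC2", "MPO", "NTRK1",
)

#: genes made perfectly rank-correlated within the control group; the 28
#: induced pairs split into 6 curated and 22 novel edges
PERFECT_CLUSTER = ("CTSC", "CTSD", "SERPINA3", "CASP4", "A2M", "MPO", "GNB1", "PRKCG")


def curated_edges_path() -> Path:
    return Path(resources.files("dcoex").joinpath("data/curated_edges_synthetic.sif"))


def curated_edges() -> list[tuple[str, str, str]]:
    return read_sif(curated_edges_path())


def _complement(p: tuple[int, ...]) -> tuple[int, ...]:
    # the rank pattern with Spearman rho = -1 against p
    return tuple(6 - v for v in p)


def _distinct_permutations(rng: np.random.Generator, k: int,
                           forbidden: set[tuple[int, ...]]) -> list[tuple[int, ...]]:
    """Draw k rank patterns of (1..5), no two with |rho| = 1 (i.e. no two
    equal or rank-complementary), avoiding ``forbidden`` patterns too."""
    chosen: list[tuple[int, ...]] = []
    taken = set(forbidden) | {_complement(f) for f in forbidden}
    while len(chosen) < k:
        p = tuple(int(v) for v in rng.permutation(5) + 1)
        if p in taken:
            continue
        chosen.append(p)
        taken.add(p)
        taken.add(_complement(p))
    return chosen


def demo_network_inputs(seed: int = 7) -> tuple[pd.DataFrame, pd.Series, list]:
    """Expression (genes x 10 cases), group labels, and the curated triples.

    Within the control arm every gene carries a distinct rank pattern of
    (1..5) except the :data:`PERFECT_CLUSTER` genes, which share one pattern
    (rho = 1, exact two-sided p = 2/120).  Within the case arm all 23
    patterns are distinct, so no pair is perfectly monotone there.  Small
    positive offsets keep values strictly positive and gene-specific.
    """
    rng = np.random.default_rng(seed)
    case_ids = [f"C{i}" for i in range(5)] + [f"P{i}" for i in range(5)]
    groups = pd.Series(["control"] * 5 + ["case"] * 5, index=case_ids)

    cluster = set(PERFECT_CLUSTER)
    others = [g for g in DEMO_GENES if g not in cluster]

    cluster_pattern = (1, 3, 2, 5, 4)
    other_patterns = _distinct_permutations(rng, len(others), {cluster_pattern})
    control_pattern = {g: cluster_pattern for g in cluster}
    control_pattern.update(dict(zip(others, other_patterns)))

    case_patterns = _distinct_permutations(rng, len(DEMO_GENES), set())
    case_pattern = dict(zip(DEMO_GENES, case_patterns))

    data = {}
    for i, gene in enumerate(DEMO_GENES):
        offset = 10.0 + i  # keeps genes on distinct positive scales
        row = [offset + v for v in control_pattern[gene]]
        row += [offset + v for v in case_pattern[gene]]
        data[gene] = row
    expr = pd.DataFrame.from_dict(data, orient="index", columns=case_ids)

    # defensive: confirm the construction invariants the docstring states
    ctrl = expr[case_ids[:5]]
    case = expr[case_ids[5:]]
    for sub, expect_perfect in ((ctrl, True), (case, False)):
        perfect = set()
        for ga, gb in itertools.combinations(DEMO_GENES, 2):
            rho = np.corrcoef(
                pd.Series(sub.loc[ga]).rank(), pd.Series(sub.loc[gb]).rank()
            )[0, 1]
            if abs(rho) > 1 - 1e-9:
                perfect.add(frozenset((ga, gb)))
        if expect_perfect:
            want = {frozenset(p) for p in itertools.combinations(PERFECT_CLUSTER, 2)}
            assert perfect == want, "control-arm monotone pairs drifted from design"
        else:
            assert not perfect, "case arm must contain no perfectly monotone pair"

    return expr, groups, curated_edges()
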