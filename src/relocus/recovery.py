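"""Parameter-recovery benchmarks on the synthetic fixture.

These helpers re-estimate the generator's configured effect sizes from
simulated counts the same way a real analysis would (normalize, then ratio
of group means), averaging over independently seeded simulations.  They
back both the package's self-tests and the reproduction script.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from . import sim
from .expression import differential, percent_reduction, prefilter

__all__ = ["deletion_effect_estimates", "stage_fold_change"]


def _seed_list(n_seeds: int, base_seed: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % 2**31 for s in ss.generate_state(n_seeds)]


def deletion_effect_estimates(
    genotype: str,
    tissue: str,
    stage: str,
    n_per_group: int,
    genes: Sequence[str],
    n_seeds: int = 20,
    base_seed: int = 0,
) -> dict[str, float]:
    """Mean estimated percent reduction per gene over ``n_seeds`` simulations.

    Each simulation draws WT and mutant groups (``n_per_group`` replicates
    each) at the given tissue/stage and runs normalize + percent_reduction.
    """
    ann = sim.generate_annotation(sim.SyntheticConfig(seed=0))
    acc: dict[str, list[float]] = {g: [] for g in genes}
    for seed in _seed_list(n_seeds, base_seed):
        cfg = sim.SyntheticConfig(seed=seed)
        counts, meta = sim.generate_expression(
            cfg, ann,
            [(tissue, stage, "WT", n_per_group),
             (tissue, stage, genotype, n_per_group)],
        )
        wt = list(meta.loc[meta["genotype"] == "WT", "sample_id"])
        mut = list(meta.loc[meta["genotype"] == genotype, "sample_id"])
        for g in genes:
            acc[g].append(percent_reduction(counts, g, wt, mut))
    return {g: float(np.mean(v)) for g, v in acc.items()}


def stage_fold_change(
    genes: Iterable[str] | None = None,
    stage_a: str = "p6",
    stage_b: str = "L1",
    n_a: int = 3,
    n_b: int = 4,
    n_seeds: int = 20,
    base_seed: int = 0,
) -> float:
    """Mean linear fold change across genes for a WT stage contrast.

    Runs the differential stage on fresh simulations and averages the
    per-gene linear fold changes (defaults: the five casein-like genes,
    p6 vs L1 in mammary tissue).
    """
    genes = list(genes) if genes is not None else list(sim.CASEIN_GENES)
    ann = sim.generate_annotation(sim.SyntheticConfig(seed=0))
    fcs = []
    for seed in _seed_list(n_seeds, base_seed):
        cfg = sim.SyntheticConfig(seed=seed)
        counts, meta = sim.generate_expression(
            cfg, ann,
            [("mammary", stage_a, "WT", n_a), ("mammary", stage_b, "WT", n_b)],
        )
        cols_a = list(meta.loc[meta["stage"] == stage_a, "sample_id"])
        cols_b = list(meta.loc[meta["stage"] == stage_b, "sample_id"])
        res = differential(prefilter(counts), cols_a, cols_b)
        fcs.append(float((2.0 ** res.loc[genes, "log2_fold_change"]).mean()))
    return float(np.mean(fcs))
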