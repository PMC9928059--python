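"""Synthetic casein-locus-like fixture generator.

The generator emits every input the analysis pipeline consumes — gene
annotation, replicate TF peak calls, H3K27ac broad peaks, Hi-C contact
domains, a genome sequence with GAS motifs planted under known elements,
and negative-binomial RNA-seq count matrices — together with a ground-truth
manifest, so every downstream stage can be scored against truth without
downloading any real accession.

The default configuration mirrors the structure of the mouse casein locus:
eight genes (five mammary casein-like genes, a dual-specificity *Odam*-like
gene, and two salivary-specific genes) spread over ~330 kb, 20 true
regulatory elements of which 12 carry a GAS consensus, and four
super-enhancer constituents clustered in a ~10 kb span between the
*Csn1s2b*-like and *Odam*-like genes.  Effect sizes for the enhancer
deletion genotypes are the fractional-remaining expression levels the
corresponding mouse experiments report (e.g. 0.02 of wild type for the
*Csn3*-like gene after super-enhancer deletion).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "SyntheticConfig",
    "SimFixture",
    "CASEIN_GENES",
    "FOCAL_GENES",
    "STAGES",
    "GAS_PATTERN",
    "generate_annotation",
    "generate_domains",
    "generate_peaks",
    "generate_sequence",
    "generate_expression",
    "generate_fixture",
    "nb_sample",
]


class ConfigError(ValueError):
    """Raised when a SyntheticConfig cannot produce a consistent fixture."""


STAGES = ("virgin", "p6", "p18", "L1", "L10")
TISSUES = ("mammary", "salivary")
CASEIN_GENES = ["Csn1s1", "Csn2", "Csn1s2a", "Csn1s2b", "Csn3"]

GAS_PATTERN = "TTCNNNGAA"  # STAT-family GAS consensus, palindromic as a pattern
_GAS_RE = re.compile("TTC[ACGT]{3}GAA")

FOCAL_CHROM = "chr5"

# (name, start, end, tissue specificity); ~330 kb total span, gene order
# mirroring the casein locus archetype.
FOCAL_GENES = [
    ("Csn1s1", 100_000, 115_000, "mammary"),
    ("Csn2", 140_000, 155_000, "mammary"),
    ("Csn1s2a", 185_000, 200_000, "mammary"),
    ("Csn1s2b", 225_000, 240_000, "mammary"),
    ("Odam", 275_000, 285_000, "dual"),
    ("Fdcsp", 300_000, 310_000, "salivary"),
    ("Prr27", 330_000, 340_000, "salivary"),
    ("Csn3", 412_000, 427_000, "mammary"),
]

# Focal regulatory elements: (name, start, planted GAS count, SE constituent).
# Spacing is chosen so that single-linkage stitching at the field-standard
# 12.5 kb gap yields exactly one >=3-constituent cluster: the four SE
# constituents in the ~10 kb span between the Csn1s2b- and Odam-like genes.
FOCAL_ELEMENTS = [
    ("Csn1s1_E1", 83_000, 0, False),
    ("Csn1s1_E2", 96_200, 1, False),
    ("Csn1s1_prom", 99_400, 1, False),
    ("Csn2_enh", 135_000, 0, False),
    ("Csn2_prom", 139_400, 1, False),
    ("Csn1s2a_prom", 184_400, 1, False),
    ("Csn1s2b_enh", 220_000, 0, False),
    ("Csn1s2b_prom", 224_400, 1, False),
    ("SE_c1", 250_500, 1, True),
    ("SE_c2", 253_200, 1, True),
    ("SE_c3", 256_100, 1, True),
    ("SE_c4", 259_000, 1, True),
    ("Odam_prom", 274_400, 1, False),
    ("Fdcsp_enh", 295_000, 0, False),
    ("Fdcsp_prom", 299_400, 0, False),
    ("Prr27_prom", 329_400, 0, False),
    ("Intergenic_enh", 370_000, 0, False),
    ("Csn3_E1", 395_000, 0, False),
    ("Csn3_E2", 408_000, 2, False),
    ("Csn3_prom", 411_400, 1, False),
]

# True elements inside background gene clusters (sparser than the focal
# locus, so it tops the element-density ranking).
BACKGROUND_ELEMENTS = [
    ("bgA_e1", "chr1", 130_000),
    ("bgC_e1", "chr2", 75_000),
]

# Decoy peaks exercising the consensus and H3K27ac filters.
_DECOYS_REP1_ONLY = [("chr5", 440_000), ("chr1", 20_000), ("chr2", 150_000)]
_DECOYS_REP2_ONLY = [("chr5", 445_000), ("chr1", 40_000)]
_DECOYS_NO_K27 = [("chr5", 30_000), ("chr1", 250_000)]

# H3K27ac regions with no TF peak underneath (plain acetylated chromatin).
_EXTRA_BROAD = [("chr5", 310_500, 312_500), ("chr1", 60_000, 62_000)]

_CHROM_SIZES = {"chr1": 400_000, "chr2": 200_000, "chr5": 500_000}

_BACKGROUND_GENES = [
    # cluster A: six induced genes straddling the chr1 domain border at 150 kb
    ("bgA1", "chr1", 90_000, 98_000, "clusterA"),
    ("bgA2", "chr1", 104_000, 112_000, "clusterA"),
    ("bgA3", "chr1", 118_000, 126_000, "clusterA"),
    ("bgA4", "chr1", 160_000, 168_000, "clusterA"),
    ("bgA5", "chr1", 174_000, 182_000, "clusterA"),
    ("bgA6", "chr1", 188_000, 196_000, "clusterA"),
    # non-induced interloper separating clusters A and B in gene order
    ("bgX1", "chr1", 230_000, 240_000, "interloper"),
    # cluster B: two induced genes crossing the chr1 border at 320 kb
    ("bgB1", "chr1", 300_000, 310_000, "clusterB"),
    ("bgB2", "chr1", 330_000, 340_000, "clusterB"),
    # cluster C: four induced genes inside one chr2 domain
    ("bgC1", "chr2", 50_000, 58_000, "clusterC"),
    ("bgC2", "chr2", 64_000, 72_000, "clusterC"),
    ("bgC3", "chr2", 78_000, 86_000, "clusterC"),
    ("bgC4", "chr2", 92_000, 100_000, "clusterC"),
    # non-induced neighbours flanking the focal locus on chr5
    ("NbrUp", "chr5", 40_000, 50_000, "neighbor"),
    ("NbrDn", "chr5", 460_000, 470_000, "neighbor"),
]

# Stage-effect profiles: expected-count multiplier relative to the p6 stage.
# The casein profile realises the ~100-fold p6 -> L1 induction and the
# >= 1e4-fold virgin -> L10 span of the milk-protein genes.
_STAGE_PROFILES: dict[str, dict[str, float]] = {
    "casein": {"virgin": 0.01, "p6": 1.0, "p18": 30.0, "L1": 100.0, "L10": 120.0},
    "odam": {"virgin": 0.1, "p6": 1.0, "p18": 15.0, "L1": 20.0, "L10": 20.0},
    "minor": {"virgin": 0.5, "p6": 1.0, "p18": 5.0, "L1": 12.0, "L10": 12.0},
    "induced_bg": {"virgin": 1.0, "p6": 1.0, "p18": 6.0, "L1": 20.0, "L10": 20.0},
    "flat": {s: 1.0 for s in STAGES},
}


def _default_base_expression() -> dict[tuple[str, str], float]:
    """Expected count at the p6 reference stage, per (gene, tissue)."""
    base: dict[tuple[str, str], float] = {}
    mammary = {
        "Csn1s1": 1500.0, "Csn2": 1800.0, "Csn1s2a": 1200.0,
        "Csn1s2b": 900.0, "Csn3": 1200.0,
        "Odam": 150.0, "Fdcsp": 25.0, "Prr27": 25.0,
    }
    salivary = {
        "Csn1s1": 5.0, "Csn2": 5.0, "Csn1s2a": 5.0, "Csn1s2b": 5.0,
        "Csn3": 60.0, "Odam": 3000.0, "Fdcsp": 20_000.0, "Prr27": 5_000.0,
    }
    for g, v in mammary.items():
        base[(g, "mammary")] = v
    for g, v in salivary.items():
        base[(g, "salivary")] = v
    for name, _c, _s, _e, grp in _BACKGROUND_GENES:
        v = 400.0 if grp in ("neighbor", "interloper") else 300.0
        base[(name, "mammary")] = v
        base[(name, "salivary")] = v
    return base


def _default_stage_profile_map() -> dict[tuple[str, str], str]:
    prof: dict[tuple[str, str], str] = {}
    for g in CASEIN_GENES:
        prof[(g, "mammary")] = "casein"
    prof[("Odam", "mammary")] = "odam"
    prof[("Fdcsp", "mammary")] = "minor"
    prof[("Prr27", "mammary")] = "minor"
    for name, _c, _s, _e, grp in _BACKGROUND_GENES:
        prof[(name, "mammary")] = "induced_bg" if grp.startswith("cluster") else "flat"
    # salivary tissue is profiled at lactation only; expression kept flat
    return prof


def _default_genotype_effects() -> dict[tuple[str, str], dict[str, float]]:
    """Fraction of wild-type expression per (genotype, tissue) -> gene.

    Values are the fractional-remaining levels the corresponding mouse
    deletion lines report: e.g. super-enhancer deletion (dSE) leaves 2% of
    Csn3-like, 0.5% of Odam-like, 7% of Csn1s2b-like and 50% of Csn1s1-like
    expression in mammary tissue.
    """
    return {
        ("dSE", "mammary"): {
            "Csn3": 0.02, "Odam": 0.005, "Csn1s2b": 0.07,
            "Csn1s1": 0.50, "Csn2": 0.60, "Csn1s2a": 0.60,
        },
        ("dSE", "salivary"): {"Fdcsp": 0.01, "Csn3": 0.12, "Odam": 0.0},
        ("dE1", "mammary"): {"Csn3": 0.55},
        ("dE2", "mammary"): {"Csn3": 0.50},
        ("dE12", "mammary"): {"Csn3": 0.02},
        ("dE4", "mammary"): {},
        ("dE2-S", "mammary"): {"Csn3": 0.02},
        ("dE2-SN", "mammary"): {"Csn3": 0.01},
        ("dOdam", "mammary"): {"Odam": 0.0, "Csn3": 2.0},
        ("dOdam", "salivary"): {"Odam": 0.0},
        ("Csn1s1-dE1", "mammary"): {},
        ("Csn1s1-dE2", "mammary"): {"Csn1s1": 0.35},
    }


def _default_genotype_effects_p6() -> dict[tuple[str, str], dict[str, float]]:
    # In early pregnancy the SE controls the whole shared locus: every
    # casein-like gene and the Odam-like gene drop by ~98% in dSE tissue.
    genes = CASEIN_GENES + ["Odam"]
    return {("dSE", "mammary"): {g: 0.02 for g in genes}}


_DEFAULT_DESIGN = [
    ("mammary", "p6", "WT", 3),
    ("mammary", "L1", "WT", 4),
    ("mammary", "L10", "WT", 4),
    ("salivary", "L1", "WT", 4),
]


@dataclass
class SyntheticConfig:
    """All knobs of the fixture generator.

    Defaults realise the study conditions: locus geometry, element counts,
    deletion effect sizes and replicate numbers are those of the casein-locus
    experiments the pipeline is designed around.
    """

    seed: int = 0
    element_width: int = 300
    replicate_jitter_bp: int = 20
    n_elements_focal: int = 20
    n_gas_positive_elements: int = 12
    se_constituents: int = 4
    n_background_clusters: int = 3
    n_housekeeping: int = 280
    nb_dispersion: float = 0.02
    library_size_range: tuple[float, float] = (0.7, 1.3)
    design: list[tuple[str, str, str, int]] = field(
        default_factory=lambda: list(_DEFAULT_DESIGN)
    )
    base_expression: dict[tuple[str, str], float] = field(
        default_factory=_default_base_expression
    )
    stage_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _STAGE_PROFILES.items()}
    )
    stage_profile_map: dict[tuple[str, str], str] = field(
        default_factory=_default_stage_profile_map
    )
    genotype_effects: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=_default_genotype_effects
    )
    genotype_effects_p6: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=_default_genotype_effects_p6
    )

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.n_gas_positive_elements > self.n_elements_focal:
            raise ConfigError(
                "n_gas_positive_elements cannot exceed n_elements_focal"
            )
        if self.element_width < len(GAS_PATTERN):
            raise ConfigError("elements must be at least as long as the GAS motif")
        if self.replicate_jitter_bp * 2 >= self.element_width:
            raise ConfigError("replicate jitter would destroy replicate overlap")
        for effects in (self.genotype_effects, self.genotype_effects_p6):
            for table in effects.values():
                for gene, frac in table.items():
                    if frac < 0:
                        raise ConfigError(
                            f"negative fractional effect for {gene}: {frac}"
                        )

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# annotation & domains
# ---------------------------------------------------------------------------

def chrom_sizes(cfg: SyntheticConfig) -> dict[str, int]:
    sizes = dict(_CHROM_SIZES)
    sizes["chr3"] = 10_000 + cfg.n_housekeeping * 3_500
    return sizes


def generate_annotation(cfg: SyntheticConfig) -> pd.DataFrame:
    """Protein-coding gene annotation for the focal and background loci.

    Returns a frame with columns gene_id, chrom, start, end, strand,
    biotype, tissue_spec, group, in 0-based half-open coordinates.
    """
    rows = []
    for name, start, end, spec in FOCAL_GENES:
        rows.append((name, FOCAL_CHROM, start, end, "+", "protein_coding", spec, "focal"))
    for name, chrom, start, end, grp in _BACKGROUND_GENES:
        rows.append((name, chrom, start, end, "+", "protein_coding", "none", grp))
    for i in range(cfg.n_housekeeping):
        start = 5_000 + i * 3_500
        rows.append(
            (f"hk{i:03d}", "chr3", start, start + 2_000, "+", "protein_coding",
             "none", "housekeeping")
        )
    ann = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "biotype",
                 "tissue_spec", "group"],
    )
    sizes = chrom_sizes(cfg)
    for chrom, sub in ann.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["end"].values[:-1] > sub["start"].values[1:]).any():
            raise ConfigError(f"overlapping genes on {chrom}")
        if sub["end"].max() > sizes[chrom]:
            raise ConfigError(f"gene beyond end of {chrom}")
    ann = ann.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    focal = ann[ann["group"] == "focal"]
    span = focal["end"].max() - focal["start"].min()
    if not 300_000 <= span <= 360_000:
        raise ConfigError(f"focal locus span {span} outside 300-360 kb")
    return ann


def generate_domains(cfg: SyntheticConfig) -> list[GenomicInterval]:
    """Non-overlapping Hi-C contact domains tiling every chromosome.

    The focal locus sits entirely inside one chr5 domain; background
    cluster A straddles the chr1 border at 150 kb and cluster B the border
    at 320 kb, exercising the split and discard rules.
    """
    doms = [
        GenomicInterval("chr1", 0, 150_000),
        GenomicInterval("chr1", 150_000, 320_000),
        GenomicInterval("chr1", 320_000, 400_000),
        GenomicInterval("chr2", 0, 200_000),
        GenomicInterval("chr5", 0, 70_000),
        GenomicInterval("chr5", 70_000, 450_000),
        GenomicInterval("chr5", 450_000, 500_000),
    ]
    size3 = chrom_sizes(cfg)["chr3"]
    edges = list(range(0, size3, 200_000)) + [size3]
    for a, b in zip(edges, edges[1:]):
        if b > a:
            doms.append(GenomicInterval("chr3", a, b))
    return doms


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, start: int, end: int, j: int) -> tuple[int, int]:
    ds, de = rng.integers(-j, j + 1, size=2)
    return int(start + ds), int(end + de)


def generate_peaks(cfg: SyntheticConfig) -> tuple[dict[str, pd.DataFrame], dict]:
    """Peak calls per factor plus the ground-truth element manifest.

    Every true element appears in both STAT5A replicates (independently
    jittered, overlap guaranteed) and under an H3K27ac broad peak.  Decoys
    appear in a single replicate or without acetylation support and must be
    rejected by the consensus/filter stages.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    w = cfg.element_width
    j = cfg.replicate_jitter_bp

    truth_elements = []
    for name, start, gas, is_se in FOCAL_ELEMENTS:
        truth_elements.append(
            dict(name=name, chrom=FOCAL_CHROM, start=start, end=start + w,
                 gas_count=gas, se_constituent=is_se, focal=True)
        )
    for name, chrom, start in BACKGROUND_ELEMENTS:
        truth_elements.append(
            dict(name=name, chrom=chrom, start=start, end=start + w,
                 gas_count=0, se_constituent=False, focal=False)
        )

    rep1_rows, rep2_rows = [], []
    for el in truth_elements:
        score = float(rng.uniform(500, 900)) if el["se_constituent"] else float(
            rng.uniform(200, 600)
        )
        s1, e1 = _jitter(rng, el["start"], el["end"], j)
        s2, e2 = _jitter(rng, el["start"], el["end"], j)
        el["rep1"] = [s1, e1]
        el["rep2"] = [s2, e2]
        el["score"] = round(score, 1)
        rep1_rows.append((el["chrom"], s1, e1, el["name"], el["score"]))
        rep2_rows.append((el["chrom"], s2, e2, el["name"], el["score"]))

    for i, (chrom, start) in enumerate(_DECOYS_REP1_ONLY):
        rep1_rows.append((chrom, start, start + w, f"decoy_r1_{i}", 150.0))
    for i, (chrom, start) in enumerate(_DECOYS_REP2_ONLY):
        rep2_rows.append((chrom, start, start + w, f"decoy_r2_{i}", 150.0))
    for i, (chrom, start) in enumerate(_DECOYS_NO_K27):
        s1, e1 = _jitter(rng, start, start + w, j)
        s2, e2 = _jitter(rng, start, start + w, j)
        rep1_rows.append((chrom, s1, e1, f"decoy_nok27_{i}", 180.0))
        rep2_rows.append((chrom, s2, e2, f"decoy_nok27_{i}", 180.0))

    cols = ["chrom", "start", "end", "name", "score"]
    peaks: dict[str, pd.DataFrame] = {}
    peaks["STAT5A_rep1"] = pd.DataFrame(rep1_rows, columns=cols)
    peaks["STAT5A_rep2"] = pd.DataFrame(rep2_rows, columns=cols)

    # H3K27ac broad peaks: +-500 bp around every true element, merged, plus
    # a couple of TF-free acetylated regions.
    from .intervals import merge

    broad_iv = merge(
        [GenomicInterval(el["chrom"], el["start"] - 500, el["end"] + 500)
         for el in truth_elements],
        max_gap=0,
    )
    broad_rows = [(iv.chrom, iv.start, iv.end, f"k27_{i}", 400.0)
                  for i, iv in enumerate(broad_iv)]
    broad_rows += [(c, s, e, f"k27_x{i}", 300.0)
                   for i, (c, s, e) in enumerate(_EXTRA_BROAD)]
    peaks["H3K27ac"] = pd.DataFrame(broad_rows, columns=cols).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)

    # auxiliary factor tracks (not used by the core pipeline; emitted for
    # completeness of the fixture)
    by_name = {el["name"]: el for el in truth_elements}

    def _subset(names: Iterable[str]) -> pd.DataFrame:
        rows = [(by_name[n]["chrom"], by_name[n]["start"], by_name[n]["end"],
                 n, by_name[n]["score"]) for n in names]
        return pd.DataFrame(rows, columns=cols)

    se_names = [n for n, *_ in FOCAL_ELEMENTS if by_name[n]["se_constituent"]]
    peaks["GR"] = _subset(["Csn3_E1", "Csn1s1_E2"] + se_names)
    peaks["NFIB"] = _subset(["Csn3_E2", "Csn1s1_E2"] + se_names)
    peaks["MED1"] = _subset(se_names)
    prom_names = [n for n, *_ in FOCAL_ELEMENTS if n.endswith("_prom")]
    peaks["H3K4me3"] = _subset(prom_names)
    enh_names = [n for n, *_ in FOCAL_ELEMENTS if not n.endswith("_prom")]
    peaks["H3K4me1"] = _subset(enh_names)
    polii = [(FOCAL_CHROM, s, e, g, 500.0)
             for g, s, e, spec in FOCAL_GENES if g in CASEIN_GENES]
    peaks["PolII"] = pd.DataFrame(polii, columns=cols)

    truth = {
        "elements": truth_elements,
        "se_constituents": se_names,
        "focal_span": [FOCAL_CHROM, FOCAL_GENES[0][1], FOCAL_GENES[-1][2]],
    }
    n_focal = sum(el["focal"] for el in truth_elements)
    if n_focal != cfg.n_elements_focal:
        raise ConfigError(
            f"geometry provides {n_focal} focal elements, "
            f"config asks for {cfg.n_elements_focal}"
        )
    n_gas = sum(1 for el in truth_elements if el["gas_count"] > 0 and el["focal"])
    if n_gas != cfg.n_gas_positive_elements:
        raise ConfigError(
            f"geometry provides {n_gas} GAS-positive elements, "
            f"config asks for {cfg.n_gas_positive_elements}"
        )
    return peaks, truth


# ---------------------------------------------------------------------------
# sequence
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_sequence(cfg: SyntheticConfig, truth: dict) -> dict[str, str]:
    """I.i.d. uniform ACGT genome with GAS motifs planted under elements.

    Exactly the configured number of elements carry at least one planted
    TTCNNNGAA instance (concrete N bases); every other element window is
    scrubbed so the scanner finds no spurious consensus within the jitter
    margin of any GAS-negative element.  Background occurrences outside
    element windows are left alone.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    seqs: dict[str, np.ndarray] = {}
    for chrom, size in sorted(chrom_sizes(cfg).items()):
        seqs[chrom] = _BASES[rng.integers(0, 4, size=size)].copy()

    margin = cfg.replicate_jitter_bp + len(GAS_PATTERN) - 1
    for el in truth["elements"]:
        arr = seqs[el["chrom"]]
        if el["end"] - el["start"] < len(GAS_PATTERN):
            raise ConfigError(f"element {el['name']} shorter than the GAS motif")
        center = (el["start"] + el["end"]) // 2
        wanted: list[int] = []
        if el["gas_count"] > 0:
            offsets = np.linspace(-30 * (el["gas_count"] - 1) / 2,
                                  30 * (el["gas_count"] - 1) / 2,
                                  el["gas_count"])
            wanted = [int(center + o) - 4 for o in offsets]
        win_s = max(0, el["start"] - margin)
        win_e = min(len(arr), el["end"] + margin)
        _enforce_gas(arr, win_s, win_e, wanted, rng)
        el["gas_positions"] = wanted
    return {c: a.tobytes().decode("ascii") for c, a in seqs.items()}


def _enforce_gas(
    arr: np.ndarray, win_s: int, win_e: int, wanted: list[int],
    rng: np.random.Generator,
) -> None:
    """Mutate ``arr[win_s:win_e]`` until its GAS hits are exactly ``wanted``."""
    for _ in range(100):
        window = arr[win_s:win_e].tobytes().decode("ascii")
        hits = {win_s + m.start() for m in _GAS_RE.finditer(window)}
        extra = hits - set(wanted)
        missing = set(wanted) - hits
        if not extra and not missing:
            return
        for pos in extra:
            arr[pos] = ord("A")  # TTC... -> ATC... kills the match
        for pos in missing:
            motif = ("TTC"
                     + "".join(rng.choice(list("ACGT"), size=3))
                     + "GAA")
            arr[pos:pos + 9] = np.frombuffer(motif.encode(), dtype=np.uint8)
    raise ConfigError("could not stabilise GAS motif content in an element")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def nb_sample(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Negative-binomial draws in mean/dispersion parameterisation.

    ``var = mean + dispersion * mean**2``; a zero mean yields zeros.
    """
    if dispersion <= 0:
        raise ConfigError("dispersion must be positive")
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


def _gene_models(cfg: SyntheticConfig, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-gene baseline means and stage profiles, deterministic in the seed."""
    rng = np.random.default_rng([cfg.seed, 4])
    rows = []
    for gene in annotation["gene_id"]:
        if gene.startswith("hk"):
            base = float(np.exp(rng.normal(np.log(200.0), 0.5)))
            bm, bs, prof = base, base, "flat"
        else:
            bm = cfg.base_expression[(gene, "mammary")]
            bs = cfg.base_expression[(gene, "salivary")]
            prof = cfg.stage_profile_map.get((gene, "mammary"), "flat")
        rows.append((gene, bm, bs, prof))
    return pd.DataFrame(
        rows, columns=["gene_id", "base_mammary", "base_salivary", "profile"]
    ).set_index("gene_id")


def _genotype_fraction(
    cfg: SyntheticConfig, genotype: str, tissue: str, stage: str, gene: str
) -> float:
    if genotype == "WT":
        return 1.0
    if stage == "p6":
        table = cfg.genotype_effects_p6.get((genotype, tissue))
        if table is not None and gene in table:
            return table[gene]
    table = cfg.genotype_effects.get((genotype, tissue), {})
    return table.get(gene, 1.0)


def expected_mean(
    cfg: SyntheticConfig, models: pd.DataFrame, gene: str, tissue: str,
    stage: str, genotype: str,
) -> float:
    row = models.loc[gene]
    if tissue == "mammary":
        base = row["base_mammary"]
        mult = cfg.stage_profiles[row["profile"]][stage]
    else:
        base = row["base_salivary"]
        mult = 1.0  # salivary expression modelled as stage-flat
    return base * mult * _genotype_fraction(cfg, genotype, tissue, stage, gene)


def generate_expression(
    cfg: SyntheticConfig,
    annotation: pd.DataFrame | None = None,
    design: Sequence[tuple[str, str, str, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix plus sample metadata.

    ``design`` lists ``(tissue, stage, genotype, n_replicates)`` groups; the
    per-sample expected count is ``baseline x stage effect x genotype
    fraction x library-size factor``.
    """
    if annotation is None:
        annotation = generate_annotation(cfg)
    if design is None:
        design = cfg.design
    models = _gene_models(cfg, annotation)
    rng = np.random.default_rng([cfg.seed, 3])

    meta_rows, columns = [], []
    lib_factors = []
    for tissue, stage, genotype, n in design:
        if tissue not in TISSUES:
            raise ConfigError(f"unknown tissue {tissue!r}")
        if stage not in STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        for r in range(1, n + 1):
            sid = f"{tissue}_{stage}_{genotype}_r{r}"
            meta_rows.append((sid, tissue, stage, genotype, r))
            columns.append(sid)
            lib_factors.append(float(rng.uniform(*cfg.library_size_range)))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "tissue", "stage", "genotype", "replicate"]
    )
    if meta["sample_id"].duplicated().any():
        raise ConfigError("duplicate (tissue, stage, genotype, replicate) in design")

    counts = np.zeros((len(models), len(columns)), dtype=np.int64)
    genes = list(models.index)
    for gi, gene in enumerate(genes):
        for si, (sid, tissue, stage, genotype, _r) in enumerate(meta_rows):
            m = expected_mean(cfg, models, gene, tissue, stage, genotype)
            counts[gi, si] = nb_sample(
                rng, m * lib_factors[si], cfg.nb_dispersion, 1
            )[0]
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=columns)
    return counts_df, meta


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SimFixture:
    """Everything the pipeline consumes, generated in memory from one seed."""

    cfg: SyntheticConfig
    annotation: pd.DataFrame
    domains: list[GenomicInterval]
    peaks: dict[str, pd.DataFrame]
    truth: dict
    sequences: dict[str, str]
    counts: pd.DataFrame
    meta: pd.DataFrame

    @property
    def manifest(self) -> dict:
        return {
            "seed": self.cfg.seed,
            "elements": self.truth["elements"],
            "se_constituents": self.truth["se_constituents"],
            "focal_span": self.truth["focal_span"],
            "genotype_effects": {
                f"{g}|{t}": table
                for (g, t), table in self.cfg.genotype_effects.items()
            },
            "genotype_effects_p6": {
                f"{g}|{t}": table
                for (g, t), table in self.cfg.genotype_effects_p6.items()
            },
        }


def generate_fixture(
    cfg: SyntheticConfig,
    design: Sequence[tuple[str, str, str, int]] | None = None,
    with_sequence: bool = True,
) -> SimFixture:
    """Generate the full fixture (annotation, domains, peaks, sequence, counts)."""
    annotation = generate_annotation(cfg)
    domains = generate_domains(cfg)
    peaks, truth = generate_peaks(cfg)
    sequences = generate_sequence(cfg, truth) if with_sequence else {}
    counts, meta = generate_expression(cfg, annotation, design)
    return SimFixture(cfg, annotation, domains, peaks, truth, sequences,
                      counts, meta)
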