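"""Synthetic data generation for every input the pipeline consumes.

Emulates the study design of a two-line (HAB vs LAB) brain-region
transcriptome comparison: dye-swapped two-colour arrays with
intensity-dependent dye bias and sub-array offsets, single-channel
expression matrices with per-sample scale factors, qPCR crossing-point
plates with housekeeping genes, clustered allelic-variant tables, and
group-structured behavioral scores.  Every generator emits its ground
truth alongside the data so downstream stages are testable without
external data.

All randomness flows from ``SynthConfig.seed`` through
:func:`numpy.random.default_rng`; identical configs produce bit-identical
output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .twocolor import TwoColorArray

DEFAULT_REGIONS = ("Cg", "NAc", "PVN", "SON", "BLA", "CeA", "DG")
DEFAULT_HK_GENES = ("Gapdh", "Hprt1", "Atp2b1", "Rpl13a", "Polr2b")

__all__ = [
    "SynthConfig",
    "make_twocolor_arrays",
    "make_null_selfhyb_arrays",
    "make_singlechannel_matrix",
    "make_qpcr_plate",
    "make_variant_table",
    "make_allele_pair",
    "make_behavior_table",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 24,192 probes per array, ten
    technical-replicate slides per brain region (dye-swap balanced),
    seven limbic regions, ~300 truly line-regulated probes with fold
    changes of at least 1.4, log2-scale Gaussian noise.
    """

    seed: int
    n_probes: int = 24192
    n_arrays_per_region: int = 10
    regions: tuple[str, ...] = DEFAULT_REGIONS
    n_de_probes: int = 300
    de_fold_range: tuple[float, float] = (1.4, 6.0)
    dye_bias_amplitude: float = 0.3  # log2 units, smooth function of A
    subarray_sd: float = 0.10       # log2 units, per-block offsets
    noise_sd: float = 0.15          # log2 units, per-spot Gaussian noise
    n_subarrays: int = 16
    baseline_a_range: tuple[float, float] = (6.0, 14.0)
    # single-channel path
    n_samples_per_group: int = 6
    scale_factor_sd: float = 0.5    # log2 per-sample loading offsets
    # qPCR
    qpcr_groups: tuple[tuple[str, int], ...] = (("HAB", 8), ("LAB", 8))
    hk_genes: tuple[str, ...] = DEFAULT_HK_GENES
    cp_sd: float = 0.1              # cycles, per-well Gaussian noise
    cp_intercept: float = 22.0      # cycles at relative expression 1
    sample_loading_sd: float = 0.5  # cycles, per-sample RNA loading offset
    # behavior
    behavior_groups: tuple[str, ...] = ("WT", "HET", "KO")
    behavior_n: int = 15            # per genotype x sex
    behavior_effect: tuple[tuple[str, tuple[float, float, float]], ...] = (
        ("inner_zone_time", (0.0, 0.0, 0.0)),
    )  # endpoint -> per-genotype location shift in SD units
    # variant planting: tuple of spec dicts, see plant_variants
    variant_model: tuple = ()

    def __post_init__(self) -> None:
        if self.n_de_probes > self.n_probes:
            raise ValueError("n_de_probes must not exceed n_probes")
        for name in ("dye_bias_amplitude", "subarray_sd", "noise_sd",
                     "cp_sd", "scale_factor_sd", "sample_loading_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.de_fold_range
        if lo <= 0 or hi <= 0:
            raise ValueError("fold ratios must be > 0")
        if self.n_arrays_per_region % 2:
            raise ValueError("n_arrays_per_region must be even (dye-swap pairs)")

    def rng(self, *context: str | int) -> np.random.Generator:
        """Deterministic stream for a named sub-task of this config."""
        keys = [self.seed & 0x7FFFFFFF]
        for c in context:
            if isinstance(c, str):
                keys.append(zlib.crc32(c.encode()) & 0x7FFFFFFF)
            else:
                keys.append(int(c) & 0x7FFFFFFF)
        return np.random.default_rng(keys)


# ---------------------------------------------------------------------------
# shared ground truth

def _probe_ids(n: int) -> np.ndarray:
    return np.array([f"P{i:06d}" for i in range(n)], dtype=object)


def truth_table(cfg: SynthConfig) -> pd.DataFrame:
    """True HAB/LAB expression ratio per probe, shared across regions.

    Exactly ``cfg.n_de_probes`` probes carry a nonzero log2 ratio whose
    magnitude is log-uniform over ``de_fold_range`` with random sign;
    all other probes have ratio 1.
    """
    rng = cfg.rng("truth")
    log2_ratio = np.zeros(cfg.n_probes)
    de_idx = rng.choice(cfg.n_probes, size=cfg.n_de_probes, replace=False)
    lo, hi = cfg.de_fold_range
    mag = 2.0 ** rng.uniform(np.log2(lo), np.log2(hi), size=cfg.n_de_probes)
    sign = rng.choice([-1.0, 1.0], size=cfg.n_de_probes)
    log2_ratio[de_idx] = sign * np.log2(mag)
    return pd.DataFrame({
        "probe_id": _probe_ids(cfg.n_probes),
        "log2_ratio": log2_ratio,
        "ratio": 2.0 ** log2_ratio,
        "is_de": log2_ratio != 0.0,
    })


def _baseline_a(cfg: SynthConfig) -> np.ndarray:
    lo, hi = cfg.baseline_a_range
    return cfg.rng("baseline").uniform(lo, hi, size=cfg.n_probes)


def _blocks(cfg: SynthConfig) -> np.ndarray:
    return (np.arange(cfg.n_probes) * cfg.n_subarrays) // cfg.n_probes


def dye_bias_curve(cfg: SynthConfig, a: np.ndarray) -> np.ndarray:
    """Smooth intensity-dependent dye bias: amplitude * sin(pi * A / A_max)."""
    _, hi = cfg.baseline_a_range
    return cfg.dye_bias_amplitude * np.sin(np.pi * a / hi)


# ---------------------------------------------------------------------------
# two-colour arrays

def _build_arrays(cfg: SynthConfig, region: str, log2_ratio: np.ndarray,
                  stream: str) -> list[TwoColorArray]:
    """Spot model: M = s*ratio + dye_bias(A) + block offset + noise.

    ``s`` is +1 when HAB is on Cy5 and -1 on the dye-swapped half, so
    the dye bias and block offsets are dye-anchored (they do not flip
    with the sample orientation), exactly the artefact the dye-swap
    design cancels.
    """
    a = _baseline_a(cfg)
    blocks = _blocks(cfg)
    bias = dye_bias_curve(cfg, a)
    ids = _probe_ids(cfg.n_probes)
    n_arr = cfg.n_arrays_per_region
    rng = cfg.rng(stream, region)
    arrays = []
    for k in range(n_arr):
        hab_on_cy5 = k < n_arr // 2
        s = 1.0 if hab_on_cy5 else -1.0
        block_off = rng.normal(0.0, cfg.subarray_sd, size=cfg.n_subarrays) \
            if cfg.subarray_sd > 0 else np.zeros(cfg.n_subarrays)
        noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_probes) \
            if cfg.noise_sd > 0 else np.zeros(cfg.n_probes)
        m = s * log2_ratio + bias + block_off[blocks] + noise
        r = 2.0 ** (a + m / 2.0)
        g = 2.0 ** (a - m / 2.0)
        spots = pd.DataFrame({
            "probe_id": ids,
            "block": blocks,
            "row": np.arange(cfg.n_probes) // 192,
            "col": np.arange(cfg.n_probes) % 192,
            "R": r,
            "G": g,
        })
        arrays.append(TwoColorArray(
            spots=spots,
            orientation="HAB" if hab_on_cy5 else "LAB",
            array_id=f"{region}-{stream}-{k:02d}",
        ))
    return arrays


def make_twocolor_arrays(cfg: SynthConfig, region: str
                         ) -> tuple[list[TwoColorArray], pd.DataFrame]:
    """Dye-swap balanced technical-replicate arrays for one brain region.

    Returns ``cfg.n_arrays_per_region`` arrays (half HAB-on-Cy5, half
    HAB-on-Cy3) plus the shared truth table of planted line ratios.
    """
    if region not in cfg.regions:
        raise ValueError(f"unknown region {region!r}; configured: {cfg.regions}")
    truth = truth_table(cfg)
    arrays = _build_arrays(cfg, region, truth["log2_ratio"].to_numpy(), "array")
    return arrays, truth


def make_null_selfhyb_arrays(cfg: SynthConfig) -> tuple[list[TwoColorArray], pd.DataFrame]:
    """Self-hybridization negative control: the same sample on both channels.

    The true ratio is 1 for every probe; dye bias, block offsets and
    noise are still applied.  This is the pipeline's negative control.
    """
    truth = truth_table(replace(cfg, n_de_probes=0))
    arrays = _build_arrays(cfg, "selfhyb", np.zeros(cfg.n_probes), "selfhyb")
    return arrays, truth


# ---------------------------------------------------------------------------
# single-channel matrices

def make_singlechannel_matrix(cfg: SynthConfig, region: str
                              ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Probe x sample intensity matrix for the bead-array path.

    Two groups (HAB, LAB) of ``n_samples_per_group`` (at most six, the
    per-batch capacity of the emulated platform).  Planted group ratios
    mirror the two-colour truth; per-sample log2 scale factors are
    planted so normalization is non-trivial.  Returns (matrix, truth,
    scale_factors).
    """
    if region not in cfg.regions:
        raise ValueError(f"unknown region {region!r}")
    if cfg.n_samples_per_group > 6:
        raise ValueError("at most six samples of each line per batch")
    truth = truth_table(cfg)
    log2_ratio = truth["log2_ratio"].to_numpy()
    a = _baseline_a(cfg)
    rng = cfg.rng("singlechannel", region)
    n = cfg.n_samples_per_group
    scale = rng.normal(0.0, cfg.scale_factor_sd, size=2 * n) \
        if cfg.scale_factor_sd > 0 else np.zeros(2 * n)
    cols = {}
    for j in range(2 * n):
        is_hab = j < n
        mu = a + (log2_ratio / 2.0 if is_hab else -log2_ratio / 2.0)
        noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_probes) \
            if cfg.noise_sd > 0 else np.zeros(cfg.n_probes)
        name = f"{'HAB' if is_hab else 'LAB'}_{(j % n) + 1}"
        cols[name] = 2.0 ** (mu + scale[j] + noise)
    mat = pd.DataFrame(cols, index=_probe_ids(cfg.n_probes))
    mat.index.name = "probe_id"
    return mat, truth, scale


# ---------------------------------------------------------------------------
# qPCR plates

def make_qpcr_plate(cfg: SynthConfig, gene: str,
                    true_fold_by_group: dict[str, float]) -> pd.DataFrame:
    """Crossing-point plate for one target gene plus the housekeeping set.

    Well model: Cp = intercept - log2(relative expression) + loading(sample)
    + N(0, cp_sd), measured in duplicate.  Housekeeping genes have fold 1
    in every group; the per-sample loading offset is shared by all genes
    of a sample, which is exactly what housekeeping normalization removes.
    """
    if not cfg.hk_genes:
        raise ValueError("hk_genes must be nonempty")
    unknown = set(true_fold_by_group) - {g for g, _ in cfg.qpcr_groups}
    if unknown:
        raise ValueError(f"folds given for unknown groups: {sorted(unknown)}")
    rng = cfg.rng("qpcr", gene)
    rows = []
    for group, n_samples in cfg.qpcr_groups:
        fold = float(true_fold_by_group.get(group, 1.0))
        if fold <= 0:
            raise ValueError("true folds must be > 0")
        for s in range(n_samples):
            sample_id = f"{group}_{s + 1}"
            loading = rng.normal(0.0, cfg.sample_loading_sd) \
                if cfg.sample_loading_sd > 0 else 0.0
            for g, expr in [(gene, fold)] + [(hk, 1.0) for hk in cfg.hk_genes]:
                for rep in (1, 2):
                    noise = rng.normal(0.0, cfg.cp_sd) if cfg.cp_sd > 0 else 0.0
                    cp = cfg.cp_intercept - np.log2(expr) + loading + noise
                    rows.append((g, sample_id, group, rep, cp))
    return pd.DataFrame(rows, columns=["gene", "sample", "group", "replicate", "Cp"])


# ---------------------------------------------------------------------------
# variant tables and allele sequences

def make_variant_table(cfg: SynthConfig, model) -> pd.DataFrame:
    """Plant the variants described by ``cfg.variant_model`` into a gene model.

    Thin wrapper over :func:`plant_variants` driven by the config's
    cluster specs; an empty spec yields an empty table.
    """
    return plant_variants(model, list(cfg.variant_model), rng=cfg.rng("variants"))


def plant_variants(model, specs: list[dict], rng: np.random.Generator | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """Plant variants at specified densities, including dense clusters.

    Each spec is a dict: ``{"region": label, "start": rel, "end": rel,
    "n_snp": int, "n_ins": int, "n_del": int}`` with rel coordinates in
    the gene model's TSS-relative frame (half-open span [start, end]).
    Positions are unique across the whole table.  A cluster wider than
    its host region is an input error.

    Returns an (unannotated) variant table: type, rel_position, HAB, LAB.
    """
    from .variants import GeneModel  # local import to avoid cycle
    assert isinstance(model, GeneModel)
    if rng is None:
        rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    taken: set[int] = set()
    rows = []
    for spec in specs:
        start, end = int(spec["start"]), int(spec["end"])
        host = model.span_of(spec["region"])
        if start < host[0] or end > host[1]:
            raise ValueError(
                f"cluster [{start},{end}] wider than host region "
                f"{spec['region']} {host}")
        n_total = spec.get("n_snp", 0) + spec.get("n_ins", 0) + spec.get("n_del", 0)
        candidates = [p for p in range(start, end + 1) if p != 0 and p not in taken]
        if n_total > len(candidates):
            raise ValueError("more variants requested than positions available")
        pos = sorted(rng.choice(candidates, size=n_total, replace=False).tolist())
        taken.update(pos)
        types = (["SNP"] * spec.get("n_snp", 0)
                 + ["insertion"] * spec.get("n_ins", 0)
                 + ["deletion"] * spec.get("n_del", 0))
        rng.shuffle(types)
        for p, t in zip(pos, types):
            if t == "SNP":
                hab, lab = rng.choice(bases, size=2, replace=False)
            elif t == "insertion":
                hab, lab = "-", "".join(rng.choice(bases, size=rng.integers(1, 4)))
            else:
                hab, lab = "".join(rng.choice(bases, size=rng.integers(1, 4))), "-"
            rows.append((t, p, hab, lab))
    df = pd.DataFrame(rows, columns=["type", "rel_position", "HAB", "LAB"])
    return df.sort_values("rel_position", kind="stable").reset_index(drop=True)


def make_allele_pair(variants: pd.DataFrame, length: int,
                     seed: int = 0) -> tuple[str, str, np.ndarray]:
    """Build a (HAB, LAB) sequence pair carrying the given variants.

    ``variants`` needs columns type, rel_position (1-based offsets into
    the backbone, all within [1, length]), HAB, LAB.  The backbone
    avoids homopolymers and the bases flanking each indel are adjusted
    so a left-aligned global alignment recovers every event
    unambiguously.  Returns (hab_seq, lab_seq, hab_positions); the last
    gives each event's position in the HAB (reference) frame -- the SNP
    base or the base preceding the gap -- which drifts past the planted
    offset whenever an earlier deletion lengthens the HAB sequence.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    # backbone with no immediate repeats: keeps indel placement unambiguous
    seq = [bases[rng.integers(4)]]
    while len(seq) < length:
        b = bases[rng.integers(4)]
        if b != seq[-1]:
            seq.append(b)
    ordered = variants.sort_values("rel_position")

    def _pick(idx: int, *avoid: str) -> None:
        choices = [b for b in bases if b not in avoid]
        seq[idx] = choices[rng.integers(len(choices))]

    # de-ambiguate indel flanks: the backbone base before the event must
    # differ from the last variant base, the base after from the first,
    # otherwise left-alignment would shift the gap off its planted anchor
    for _, v in ordered.iterrows():
        p = int(v["rel_position"])
        if not 1 <= p <= length:
            raise ValueError("variant position outside sequence")
        if v["type"] == "SNP":
            continue
        vs = str(v["LAB"] if v["type"] == "insertion" else v["HAB"])
        if seq[p - 1] == vs[-1]:
            _pick(p - 1, vs[-1], seq[p - 2] if p >= 2 else "",
                  seq[p] if p < length else "")
        if p < length and seq[p] == vs[0]:
            _pick(p, vs[0], seq[p - 1],
                  seq[p + 1] if p + 1 < length else "")

    hab_parts, lab_parts = [], []
    prev = 0
    pos_used = []
    offset = 0  # extra HAB bases contributed by earlier deletions
    for _, v in ordered.iterrows():
        p = int(v["rel_position"])
        hab_parts.append("".join(seq[prev:p - 1]))
        lab_parts.append("".join(seq[prev:p - 1]))
        if v["type"] == "SNP":
            hab_parts.append(str(v["HAB"]))
            lab_parts.append(str(v["LAB"]))
            pos_used.append(p + offset)
        elif v["type"] == "insertion":
            # base(s) present in LAB, absent in HAB, after position p
            anchor = seq[p - 1]
            hab_parts.append(anchor)
            lab_parts.append(anchor + str(v["LAB"]))
            pos_used.append(p + offset)
        else:  # deletion: base(s) present in HAB, absent in LAB
            hab_parts.append(seq[p - 1] + str(v["HAB"]))
            lab_parts.append(seq[p - 1])
            pos_used.append(p + offset)
            offset += len(str(v["HAB"]))
        prev = p
    hab_parts.append("".join(seq[prev:]))
    lab_parts.append("".join(seq[prev:]))
    return "".join(hab_parts), "".join(lab_parts), np.array(pos_used)


# ---------------------------------------------------------------------------
# behavior tables

def make_behavior_table(cfg: SynthConfig) -> pd.DataFrame:
    """Behavioral endpoint table: three genotypes x two sexes.

    Endpoint values are N(10 + shift, 1) per group, with per-genotype
    location shifts (in SD units) taken from ``cfg.behavior_effect``.
    """
    if cfg.behavior_n <= 0:
        raise ValueError("behavior_n must be > 0 for every group")
    rng = cfg.rng("behavior")
    rows = []
    subject = 0
    for endpoint, shifts in cfg.behavior_effect:
        if len(shifts) != len(cfg.behavior_groups):
            raise ValueError("one shift per genotype group required")
        for sex in ("male", "female"):
            for geno, shift in zip(cfg.behavior_groups, shifts):
                vals = rng.normal(10.0 + shift, 1.0, size=cfg.behavior_n)
                for v in vals:
                    subject += 1
                    rows.append((f"S{subject:05d}", geno, sex, endpoint, v))
    return pd.DataFrame(rows, columns=["subject", "genotype", "sex", "endpoint", "value"])


# ---------------------------------------------------------------------------
# file writers (tab-delimited dialects the pipeline reads)

def write_intensity_table(array: TwoColorArray, path) -> None:
    array.spots.to_csv(path, sep="\t", index=False)


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t")


def write_cp_table(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False)
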