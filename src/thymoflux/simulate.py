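"""Synthetic data with known ground truth for every pipeline input.

Three generators emulate the statistical structure the analysis assumes:

* :func:`simulate_flux_plate` — mito-stress-test kinetic traces: per group,
  a four-level piecewise-constant OCR profile (baseline, oligomycin
  residual, FCCP maximum, Rot/AA floor) and a two-level ECAR profile, plus
  additive Gaussian measurement noise and an optional exponentially
  decaying post-injection mixing transient. Traces are scaled by each
  well's drawn cell count so that cell-number normalization is exercised;
  ground truth is returned on the normalized (per-1000-cell) scale.
* :func:`simulate_expression` — stage-structured gene expression with
  programmed pathway trajectories (peak at ISP, nadir at DP early by
  default, mirroring the developmental pattern of metabolic transcription),
  optional genes linked to a flux metric, and anticorrelated isoform pairs.
* :func:`simulate_de_table` — differential-expression statistics tables
  with known variable-gene filter outcomes.

Every generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GenePanel, MOUSE_THYMUS_SCHEME, PopulationScheme
from .flux_assay import FluxTraceSet, InjectionSchedule

__all__ = [
    "GroupFluxProfile",
    "FluxSimConfig",
    "PathwayTemplate",
    "ExprSimConfig",
    "default_flux_config",
    "default_expression_config",
    "simulate_flux_plate",
    "simulate_expression",
    "simulate_de_table",
    "basal_ocr_standard_error",
    "trajectory_template",
]


@dataclass(frozen=True)
class GroupFluxProfile:
    """True bioenergetic levels of one population, per 1000 cells.

    ``basal_ocr`` is mitochondrial basal respiration (above the
    non-mitochondrial ``nonmito_ocr`` floor); the baseline trace level is
    their sum. ``fccp_max_fold`` >= 1 guarantees nonnegative true SRC.
    """

    basal_ocr: float
    basal_ecar: float
    nonmito_ocr: float = 10.0
    oligo_residual_frac: float = 0.35
    fccp_max_fold: float = 1.5
    post_oligo_ecar_fold: float = 1.3

    def __post_init__(self) -> None:
        for name in ("basal_ocr", "basal_ecar", "nonmito_ocr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.oligo_residual_frac < 1.0:
            raise ValueError(f"oligo_residual_frac must be in (0,1), got {self.oligo_residual_frac}")
        if self.fccp_max_fold < 1.0:
            raise ValueError(f"fccp_max_fold must be >= 1, got {self.fccp_max_fold}")
        if self.post_oligo_ecar_fold <= 0:
            raise ValueError(f"post_oligo_ecar_fold must be positive, got {self.post_oligo_ecar_fold}")

    def ocr_levels(self) -> dict[str, float]:
        """Noise-free OCR trace level per phase (per 1000 cells)."""
        return {
            "baseline": self.basal_ocr + self.nonmito_ocr,
            "oligomycin": self.nonmito_ocr + self.oligo_residual_frac * self.basal_ocr,
            "fccp": self.nonmito_ocr + self.fccp_max_fold * self.basal_ocr,
            "rot_aa": self.nonmito_ocr,
        }

    def ecar_levels(self) -> dict[str, float]:
        post = self.basal_ecar * self.post_oligo_ecar_fold
        return {"baseline": self.basal_ecar, "oligomycin": post, "fccp": post, "rot_aa": post}

    def truth(self) -> dict[str, float]:
        """Ground-truth derived metrics on the normalized scale."""
        maximal = self.fccp_max_fold * self.basal_ocr
        return {
            "basal_ecar": self.basal_ecar,
            "basal_ocr": self.basal_ocr,
            "maximal_ocr": maximal,
            "src": maximal - self.basal_ocr,
            "ocr_ecar_ratio": self.basal_ocr / self.basal_ecar,
        }


# Qualitative developmental flux profile: highest in DN/ISP, minimal at
# DP early, partial recovery in SP (SP8 > SP4). Levels are per 1000 cells.
DEFAULT_GROUP_PROFILES: dict[str, GroupFluxProfile] = {
    "DN": GroupFluxProfile(basal_ocr=60.0, basal_ecar=30.0, fccp_max_fold=2.0),
    "ISP8": GroupFluxProfile(basal_ocr=55.0, basal_ecar=28.0, fccp_max_fold=1.4),
    "DP early": GroupFluxProfile(basal_ocr=15.0, basal_ecar=8.0, fccp_max_fold=1.05),
    "SP8": GroupFluxProfile(basal_ocr=35.0, basal_ecar=20.0, fccp_max_fold=1.5),
    "SP4": GroupFluxProfile(basal_ocr=28.0, basal_ecar=16.0, fccp_max_fold=1.45),
}


@dataclass(frozen=True)
class FluxSimConfig:
    """Plate-level simulation parameters.

    ``noise_sd`` is the Gaussian measurement sd on the normalized scale;
    with ``noise_relative`` it is instead a fraction of each group's
    baseline trace level (OCR) or basal ECAR (ECAR). ``transient_magnitude``
    in [0, 1) adds a carry-over of the previous phase level that decays by
    ``transient_decay`` per measurement within the new phase (off by
    default).
    """

    groups: Mapping[str, GroupFluxProfile] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROFILES)
    )
    wells_per_group: int = 4
    measurements_per_phase: int = 3
    noise_sd: float = 0.0
    noise_relative: bool = False
    transient_magnitude: float = 0.0
    transient_decay: float = 0.4
    cell_count_mean: float = 20000.0
    cell_count_sd: float = 0.0
    minutes_per_measurement: float = 6.5

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("groups must be nonempty")
        if self.wells_per_group < 1:
            raise ValueError(f"wells_per_group must be >= 1, got {self.wells_per_group}")
        if self.measurements_per_phase < 1:
            raise ValueError(f"measurements_per_phase must be >= 1, got {self.measurements_per_phase}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 <= self.transient_magnitude < 1.0:
            raise ValueError(f"transient_magnitude must be in [0,1), got {self.transient_magnitude}")
        if self.cell_count_mean <= 0:
            raise ValueError(f"cell_count_mean must be positive, got {self.cell_count_mean}")
        if self.cell_count_sd < 0:
            raise ValueError(f"cell_count_sd must be >= 0, got {self.cell_count_sd}")

    @property
    def schedule(self) -> InjectionSchedule:
        return InjectionSchedule.default(self.measurements_per_phase)


def default_flux_config(**overrides) -> FluxSimConfig:
    return FluxSimConfig(**overrides)


def _phase_sequence(levels: dict[str, float], m: int) -> np.ndarray:
    return np.concatenate(
        [np.full(m, levels[p]) for p in ("baseline", "oligomycin", "fccp", "rot_aa")]
    )


def simulate_flux_plate(
    config: FluxSimConfig, seed: int
) -> tuple[FluxTraceSet, pd.DataFrame]:
    """Simulate one plate; returns (unnormalized traces, ground truth).

    Trace values are (phase level + transient + noise) x cell_count/1000, so
    :func:`~thymoflux.flux_assay.normalize_per_well` recovers the
    per-1000-cell scale on which the returned ground-truth metrics live.
    Identical seeds give identical output.
    """
    rng = np.random.default_rng(seed)
    m = config.measurements_per_phase
    n_meas = 4 * m
    times = np.arange(n_meas) * config.minutes_per_measurement

    records = []
    cell_counts: dict[str, int] = {}
    widx = 0
    for group, prof in config.groups.items():
        ocr_levels = _phase_sequence(prof.ocr_levels(), m)
        ecar_levels = _phase_sequence(prof.ecar_levels(), m)
        if config.transient_magnitude > 0:
            for arr in (ocr_levels, ecar_levels):
                for ph in range(1, 4):
                    prev = arr[ph * m - 1]
                    for k in range(m):
                        i = ph * m + k
                        arr[i] += (
                            config.transient_magnitude
                            * (prev - arr[i])
                            * config.transient_decay**k
                        )
        sd_ocr = (
            config.noise_sd * prof.ocr_levels()["baseline"]
            if config.noise_relative
            else config.noise_sd
        )
        sd_ecar = (
            config.noise_sd * prof.basal_ecar if config.noise_relative else config.noise_sd
        )
        for _ in range(config.wells_per_group):
            widx += 1
            well = f"W{widx:02d}"
            if config.cell_count_sd > 0:
                count = max(1, int(round(rng.normal(config.cell_count_mean, config.cell_count_sd))))
            else:
                count = max(1, int(round(config.cell_count_mean)))
            cell_counts[well] = count
            scale = count / 1000.0
            ocr = (ocr_levels + rng.normal(0.0, sd_ocr, n_meas) if sd_ocr > 0 else ocr_levels) * scale
            ecar = (ecar_levels + rng.normal(0.0, sd_ecar, n_meas) if sd_ecar > 0 else ecar_levels) * scale
            for i in range(n_meas):
                records.append(
                    (well, group, "sim", i + 1, times[i], ocr[i], ecar[i])
                )
    df = pd.DataFrame(
        records,
        columns=["well", "group", "experiment", "measurement", "time_min", "ocr", "ecar"],
    )
    traces = FluxTraceSet(
        data=df, cell_counts=cell_counts, normalized=False, schedule=config.schedule
    )
    truth = pd.DataFrame({g: p.truth() for g, p in config.groups.items()}).T
    truth.index.name = "group"
    return traces, truth


def basal_ocr_standard_error(config: FluxSimConfig, group: str) -> float:
    """Analytic SE of the group-mean basal-OCR estimate under the noise model.

    The per-well estimate (mean of m baseline minus mean of m Rot/AA
    measurements) has variance 2 sd^2 / m; averaging over W wells divides
    the variance by W.
    """
    prof = config.groups[group]
    sd = (
        config.noise_sd * prof.ocr_levels()["baseline"]
        if config.noise_relative
        else config.noise_sd
    )
    m = config.measurements_per_phase
    return sd * math.sqrt(2.0 / m) / math.sqrt(config.wells_per_group)


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


def trajectory_template(
    stages: tuple[str, ...], peak_stage: str, nadir_stage: str, amplitude: float
) -> np.ndarray:
    """Piecewise-linear stage trajectory with a programmed peak and nadir.

    The early (pre-peak) stages sit on a plateau at half amplitude, the
    peak stage rises distinctly to +amplitude, the nadir falls to
    -amplitude, and the final stage recovers partway (to 0), linearly
    interpolated in stage order — the canonical developmental shape of
    metabolic transcription: high in the progenitor stages, a marked peak
    at ISP, a collapse at DP early and partial recovery in the SP stages.
    """
    if peak_stage == nadir_stage:
        raise ValueError("peak and nadir stages must differ")
    idx = {s: i for i, s in enumerate(stages)}
    for s in (peak_stage, nadir_stage):
        if s not in idx:
            raise ValueError(f"stage {s!r} not in scheme stages {list(stages)}")
    n = len(stages)
    ip, inad = idx[peak_stage], idx[nadir_stage]
    anchors = {0: 0.5 * amplitude, n - 1: 0.0}
    if 0 < ip < inad:
        anchors[ip - 1] = 0.5 * amplitude  # pre-peak plateau
    anchors[ip] = amplitude
    anchors[inad] = -amplitude
    xs = np.array(sorted(anchors))
    ys = np.array([anchors[x] for x in xs])
    return np.interp(np.arange(n), xs, ys)


@dataclass(frozen=True)
class PathwayTemplate:
    """How one simulated pathway behaves across stages.

    ``link_slope``, when set, replaces the stage trajectory of the
    pathway's genes by slope x (standardized true flux metric per
    population), creating a known expression-flux link. ``n_isoform_pairs``
    adds pairs of extra genes with mirrored (anticorrelated) trajectories,
    emulating isoenzyme switching.
    """

    n_genes: int = 8
    peak_stage: str = "ISP8"
    nadir_stage: str = "DP early"
    amplitude: float = 1.0
    link_slope: float | None = None
    n_isoform_pairs: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_isoform_pairs < 0:
            raise ValueError("gene counts must be nonnegative")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


#: Per-(composite-)population basal OCR truth used for linked genes when no
#: flux simulation supplies one; DP late sits near the DP-early nadir.
DEFAULT_FLUX_PROFILE: dict[str, float] = {
    "DN": 60.0, "ISP8": 55.0, "DP early": 15.0, "DP late": 18.0, "SP8": 35.0, "SP4": 28.0,
}


@dataclass(frozen=True)
class ExprSimConfig:
    """Expression-simulation parameters.

    ``flux_profile`` maps composite populations (DN subsets share the "DN"
    value) to the true flux metric used by linked genes. ``noise_sd`` is
    the per-measurement Gaussian sd on the expression scale;
    ``gene_offset_sd`` spreads gene baselines (constant per gene, so it
    never affects z-scores).
    """

    scheme: PopulationScheme = MOUSE_THYMUS_SCHEME
    pathways: Mapping[str, PathwayTemplate] = field(
        default_factory=lambda: {
            "glycolysis": PathwayTemplate(link_slope=1.0, n_isoform_pairs=1),
            "tca": PathwayTemplate(),
            "etc": PathwayTemplate(n_genes=6),
        }
    )
    noise_sd: float = 0.25
    flux_profile: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FLUX_PROFILE))
    flux_metric: str = "basal_ocr"
    baseline_level: float = 8.0
    gene_offset_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.gene_offset_sd < 0:
            raise ValueError("noise sds must be >= 0")


def default_expression_config(**overrides) -> ExprSimConfig:
    return ExprSimConfig(**overrides)


def _stage_flux_vector(config: ExprSimConfig) -> np.ndarray:
    """True flux metric mapped onto the scheme's stages (DN subsets share DN)."""
    scheme = config.scheme
    vals = []
    for s in scheme.stages:
        pop = "DN" if s in scheme.dn_members else s
        if pop not in config.flux_profile:
            raise ValueError(
                f"flux_profile lacks population {pop!r} needed for stage {s!r}"
            )
        vals.append(config.flux_profile[pop])
    return np.asarray(vals, dtype=float)


def simulate_expression(
    config: ExprSimConfig, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame, GenePanel]:
    """Simulate a gene x stage expression matrix with known structure.

    Returns (matrix, truth table, panel). The truth table records each
    gene's pathway, whether it is linked to the flux metric (and the
    slope), and its isoform partner if any. The panel maps each simulated
    pathway to its gene ids so the matrix can feed the trajectory and
    integration steps directly.
    """
    rng = np.random.default_rng(seed)
    scheme = config.scheme
    stages = scheme.stages
    n_stages = len(stages)

    flux = _stage_flux_vector(config)
    flux_std = (flux - flux.mean()) / flux.std(ddof=1)

    rows: dict[str, np.ndarray] = {}
    truth_rows = []
    panel: dict[str, tuple[str, ...]] = {}
    for name, tpl in config.pathways.items():
        template = trajectory_template(stages, tpl.peak_stage, tpl.nadir_stage, tpl.amplitude)
        genes = []
        for i in range(tpl.n_genes):
            gid = f"{name.upper()}{i + 1:03d}"
            offset = config.baseline_level + rng.normal(0.0, config.gene_offset_sd)
            if tpl.link_slope is not None:
                signal = tpl.link_slope * flux_std
            else:
                signal = template
            noise = rng.normal(0.0, config.noise_sd, n_stages) if config.noise_sd > 0 else 0.0
            rows[gid] = offset + signal + noise
            genes.append(gid)
            truth_rows.append(
                {
                    "gene_id": gid,
                    "pathway": name,
                    "linked": tpl.link_slope is not None,
                    "slope": tpl.link_slope if tpl.link_slope is not None else 0.0,
                    "isoform_partner": "",
                }
            )
        for k in range(tpl.n_isoform_pairs):
            ga = f"{name.upper()}ISOA{k + 1}"
            gb = f"{name.upper()}ISOB{k + 1}"
            offa = config.baseline_level + rng.normal(0.0, config.gene_offset_sd)
            offb = config.baseline_level + rng.normal(0.0, config.gene_offset_sd)
            na = rng.normal(0.0, config.noise_sd, n_stages) if config.noise_sd > 0 else 0.0
            nb = rng.normal(0.0, config.noise_sd, n_stages) if config.noise_sd > 0 else 0.0
            rows[ga] = offa + template + na
            rows[gb] = offb - template + nb
            genes.extend([ga, gb])
            truth_rows.append({"gene_id": ga, "pathway": name, "linked": False, "slope": 0.0, "isoform_partner": gb})
            truth_rows.append({"gene_id": gb, "pathway": name, "linked": False, "slope": 0.0, "isoform_partner": ga})
        panel[name] = tuple(genes)

    matrix = ExpressionMatrix(
        values=pd.DataFrame.from_dict(rows, orient="index", columns=list(stages)),
        scheme=scheme,
        scale="vst",
    )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return matrix, truth, GenePanel(pathways=panel)


# ---------------------------------------------------------------------------
# DE-table simulation
# ---------------------------------------------------------------------------

_FILTER_DEFAULTS = dict(fc_min=2.0, adj_p_max=0.01, fpkm_min=5.0, cpm_floor=0.5, mappability_min_bp=50.0)


def _brute_force_pass_set(table: pd.DataFrame, **params) -> frozenset[str]:
    """Direct predicate-by-predicate evaluation of the filter definition."""
    p = {**_FILTER_DEFAULTS, **params}
    passed = set()
    for gene, sub in table.groupby("gene_id", sort=True):
        hit = False
        for fc, ap in zip(sub["fold_change"], sub["adj_p"]):
            if (fc > p["fc_min"] or fc < 1.0 / p["fc_min"]) and ap < p["adj_p_max"]:
                hit = True
        row = sub.iloc[0]
        if (
            hit
            and row["max_fpkm"] >= p["fpkm_min"]
            and row["max_cpm"] >= p["cpm_floor"]
            and row["mappable_bp"] >= p["mappability_min_bp"]
            and not bool(row["outlier"])
        ):
            passed.add(gene)
    return frozenset(passed)


def simulate_de_table(
    n_genes: int = 100,
    pass_fraction: float = 0.3,
    seed: int = 0,
    n_contrasts: int = 3,
) -> tuple[pd.DataFrame, frozenset[str]]:
    """Simulate a DE statistics table with a known variable-gene pass set.

    Approximately ``round(n_genes * pass_fraction)`` genes are constructed
    to satisfy every filter predicate at the default thresholds; the rest
    violate a random nonempty subset of predicates. The expected pass set
    is recomputed from the emitted table by brute-force predicate
    evaluation, independent of the filter implementation.
    """
    if not 0.0 <= pass_fraction <= 1.0:
        raise ValueError(f"pass_fraction must be in [0,1], got {pass_fraction}")
    if n_genes < 0 or n_contrasts < 1:
        raise ValueError("n_genes must be >= 0 and n_contrasts >= 1")
    rng = np.random.default_rng(seed)
    n_pass = int(round(n_genes * pass_fraction))
    labels = np.zeros(n_genes, dtype=bool)
    labels[:n_pass] = True
    rng.shuffle(labels)

    contrasts = [f"c{j + 1}" for j in range(n_contrasts)]
    rows = []
    for g in range(n_genes):
        gene = f"G{g:04d}"
        # start from an unconstrained draw per contrast
        fcs = np.exp(rng.normal(0.0, 1.0, n_contrasts))
        ps = rng.uniform(0.0, 1.0, n_contrasts)
        fpkm = rng.uniform(5.5, 120.0)
        cpm = rng.uniform(0.6, 60.0)
        mappable = rng.uniform(60.0, 500.0)
        outlier = False
        if labels[g]:
            j = rng.integers(n_contrasts)
            up = rng.random() < 0.5
            strength = rng.uniform(2.2, 8.0)
            fcs[j] = strength if up else 1.0 / strength
            ps[j] = rng.uniform(1e-6, 0.008)
        else:
            broken = rng.random(5) < 0.5
            if not broken.any():
                broken[rng.integers(5)] = True
            if broken[0]:  # no contrast passes fc & p jointly
                for j in range(n_contrasts):
                    if rng.random() < 0.5:
                        fcs[j] = rng.uniform(0.55, 1.8)
                    else:
                        ps[j] = rng.uniform(0.02, 1.0)
            if broken[1]:
                fpkm = rng.uniform(0.0, 4.9)
            if broken[2]:
                cpm = rng.uniform(0.0, 0.45)
            if broken[3]:
                mappable = rng.uniform(10.0, 49.0)
            if broken[4]:
                outlier = True
        for j, c in enumerate(contrasts):
            rows.append(
                {
                    "gene_id": gene,
                    "contrast": c,
                    "fold_change": float(fcs[j]),
                    "adj_p": float(ps[j]),
                    "max_fpkm": float(fpkm),
                    "max_cpm": float(cpm),
                    "mappable_bp": float(mappable),
                    "outlier": outlier,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "contrast", "fold_change", "adj_p", "max_fpkm", "max_cpm", "mappable_bp", "outlier"],
    )
    return table, _brute_force_pass_set(table)
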