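"""Correlating gene-expression trajectories with bioenergetic flux metrics.

For one system, the per-population value of a flux metric (the mean of
well-level metrics across replicates) is asinh-transformed with a cofactor
(x -> asinh(x / c), c = 5 by default) and correlated, gene by gene, with
the z-scored expression trajectory over the same populations. Pearson R,
a two-sided p-value from the t reference distribution (n-2 df) and a BH
adjustment over the gene family classify each gene as positively
(R > threshold) or negatively (R < -threshold) correlated, or weak.

With only three populations (the organoid systems) a correlation p-value
would rest on a single degree of freedom; it is reported as undefined and
such genes are excluded from the BH family.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GenePanel, composite_dn, zscore_rows
from .stats import bh_adjust, pearson

__all__ = [
    "MatchedProfile",
    "IntegrationResult",
    "asinh_cofactor",
    "correlate_genes",
    "run_integration",
]

RESULT_COLUMNS = ("gene_id", "r", "raw_p", "adj_p", "sign_class", "significant", "n_populations", "note")


def asinh_cofactor(values, cofactor: float = 5.0) -> np.ndarray:
    """Inverse-hyperbolic-sine transform x -> asinh(x / cofactor).

    Log-like for large |x| but linear (and odd) near zero, so zero and
    small negative flux values stay well-defined. Applied to flux values
    only, never to gene z-scores.
    """
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


@dataclass(frozen=True)
class MatchedProfile:
    """Flux metric and gene z-scores aligned over the same populations."""

    populations: tuple[str, ...]
    flux: np.ndarray                # one metric value per population
    z: pd.DataFrame                 # genes x populations, z-scored
    system: str = ""
    metric: str = ""

    def __post_init__(self) -> None:
        flux = np.asarray(self.flux, dtype=float)
        object.__setattr__(self, "flux", flux)
        if len(self.populations) < 3:
            raise ValueError(f"need >= 3 populations, got {list(self.populations)}")
        if flux.size != len(self.populations):
            raise ValueError(
                f"flux vector length {flux.size} != {len(self.populations)} populations"
            )
        if tuple(self.z.columns) != tuple(self.populations):
            raise ValueError("z-matrix columns must match the population labels in order")
        if np.std(flux, ddof=1) == 0.0:
            raise ValueError("flux vector has zero variance across populations")


def correlate_genes(
    profile: MatchedProfile,
    r_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of z-scored expression with the flux vector.

    Returns one row per gene: r, two-sided raw p (NaN when n < 4), BH
    adjusted p over all genes with a defined p in this call, a sign class
    (positive / negative / weak by ``r_threshold``; undefined for constant
    expression rows, which are excluded from BH with a note), and a
    ``significant`` flag (adj_p < alpha).
    """
    n = len(profile.populations)
    rows = []
    for gene in profile.z.index:
        zrow = profile.z.loc[gene].to_numpy(dtype=float)
        if np.std(zrow, ddof=1) == 0.0:
            rows.append(
                {"gene_id": gene, "r": np.nan, "raw_p": np.nan,
                 "sign_class": "undefined", "note": "constant_expression"}
            )
            continue
        res = pearson(zrow, profile.flux)
        if res.r > r_threshold:
            cls = "positive"
        elif res.r < -r_threshold:
            cls = "negative"
        else:
            cls = "weak"
        rows.append(
            {"gene_id": gene, "r": res.r,
             "raw_p": np.nan if res.p is None else res.p,
             "sign_class": cls,
             "note": "" if res.p is not None else "p_undefined_n<4"}
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = np.nan
    defined = out["raw_p"].notna()
    if defined.any():
        out.loc[defined, "adj_p"] = bh_adjust(out.loc[defined, "raw_p"].to_numpy())
    out["significant"] = out["adj_p"] < alpha
    out["n_populations"] = n
    return out[list(RESULT_COLUMNS)]


@dataclass(frozen=True)
class IntegrationResult:
    """Per-pathway correlation tables plus a run manifest."""

    tables: Mapping[str, pd.DataFrame]
    manifest: dict


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


def flux_vector_from_summary(
    flux_summary: pd.DataFrame, metric: str
) -> dict[str, float]:
    """Extract population -> mean metric value from a tidy group summary."""
    sub = flux_summary[flux_summary["metric"] == metric]
    if len(sub) == 0:
        raise ValueError(f"flux summary has no rows for metric {metric!r}")
    return {str(g): float(m) for g, m in zip(sub["group"], sub["mean"])}


def run_integration(
    flux_summary: pd.DataFrame,
    expression: ExpressionMatrix,
    panel: GenePanel,
    metric: str = "basal_ocr",
    populations: Sequence[str] | None = None,
    cofactor: float = 5.0,
    r_threshold: float = 0.5,
    alpha: float = 0.05,
    family: str = "per-pathway",
) -> IntegrationResult:
    """Full transcriptome-flux integration for one system.

    Pipeline: composite the DN subsets of the expression matrix (using the
    scheme's weights) -> restrict both datasets to their shared populations
    (or an explicit ``populations`` subset) -> z-score gene rows across
    those populations -> asinh-transform the per-population flux means ->
    correlate each panel pathway's genes with the transformed flux.

    ``family`` controls the BH adjustment family: "per-pathway" adjusts
    within each pathway table (matching per-panel scatter plots), while
    "all-pathways" pools every gene correlation into one family.

    Raises if fewer than 3 populations are shared, listing what matched.
    """
    if family not in ("per-pathway", "all-pathways"):
        raise ValueError(f"unknown BH family {family!r}")
    flux_by_pop = flux_vector_from_summary(flux_summary, metric)

    expr = expression
    scheme = expr.scheme
    if len(scheme.dn_members) > 1 and scheme.dn_weights is not None:
        expr = composite_dn(expr)
    stage_order = [s for s in expr.scheme.stages if s in expr.values.columns]
    shared = [s for s in stage_order if s in flux_by_pop]
    if populations is not None:
        missing = [p for p in populations if p not in shared]
        if missing:
            raise ValueError(
                f"requested populations not shared by both datasets: {missing} "
                f"(shared: {shared})"
            )
        shared = [s for s in stage_order if s in set(populations)]
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared populations, matched only {shared} "
            f"(expression: {stage_order}, flux: {sorted(flux_by_pop)})"
        )

    restricted = ExpressionMatrix(
        values=expr.values[shared], scheme=expr.scheme, scale=expr.scale
    )
    zmat, constant_genes = zscore_rows(restricted)
    flux_raw = np.array([flux_by_pop[s] for s in shared], dtype=float)
    flux_t = asinh_cofactor(flux_raw, cofactor=cofactor)

    matches = panel.match(zmat.genes)
    tables: dict[str, pd.DataFrame] = {}
    for name, match in matches.items():
        if not match.present:
            raise ValueError(f"pathway {name!r} matches no genes in the expression matrix")
        profile = MatchedProfile(
            populations=tuple(shared),
            flux=flux_t,
            z=zmat.values.loc[list(match.present)],
            system=expr.scheme.system,
            metric=metric,
        )
        tables[name] = correlate_genes(profile, r_threshold=r_threshold, alpha=alpha)

    if family == "all-pathways":
        pooled = pd.concat(tables.values(), keys=tables.keys(), names=["pathway"])
        defined = pooled["raw_p"].notna()
        pooled["adj_p"] = np.nan
        if defined.any():
            pooled.loc[defined, "adj_p"] = bh_adjust(pooled.loc[defined, "raw_p"].to_numpy())
        pooled["significant"] = pooled["adj_p"] < alpha
        tables = {
            name: pooled.loc[name].reset_index(drop=True) for name in tables
        }

    manifest = {
        "system": expr.scheme.system,
        "metric": metric,
        "cofactor": cofactor,
        "r_threshold": r_threshold,
        "alpha": alpha,
        "bh_family": family,
        "populations": list(shared),
        "flux_values_raw": {s: float(v) for s, v in zip(shared, flux_raw)},
        "constant_genes": list(constant_genes),
        "pathway_coverage": {
            name: {"matched": len(m.present), "absent": list(m.absent)}
            for name, m in matches.items()
        },
        "input_digests": {
            "flux_summary": _digest(flux_summary),
            "expression": _digest(expression.values),
        },
    }
    return IntegrationResult(tables=tables, manifest=manifest)
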