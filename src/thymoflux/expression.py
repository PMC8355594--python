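"""Metabolic gene panels over ordered thymocyte developmental stages.

Expression arrives as a gene x population matrix of count-normalized,
variance-stabilized values (computed upstream; this package consumes them).
Populations follow an ordered scheme — mouse thymus runs DN1, DN2, DN3,
ISP8, DP early, DP late, SP8, SP4; human uses Thy1-3 and ISP4 — and the
double-negative (DN) stages can be composited into a single "DN" column as
a convex combination weighted by each subset's measured proportion of the
DN compartment.

The module provides row z-scoring, per-pathway mean-z trajectories,
the variable-gene filter over a precomputed differential-expression table,
and PCA of standardized expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PopulationScheme",
    "ExpressionMatrix",
    "GenePanel",
    "PanelMatch",
    "FilterResult",
    "PCAResult",
    "read_expression",
    "write_expression",
    "zscore_rows",
    "composite_dn",
    "pathway_trajectory",
    "filter_variable_genes",
    "pca_standardized",
    "MOUSE_THYMUS_SCHEME",
    "MOUSE_ATO_SCHEME",
    "HUMAN_THYMUS_SCHEME",
    "HUMAN_ATO_SCHEME",
]


@dataclass(frozen=True)
class PopulationScheme:
    """Ordered developmental stages of one system, with its DN compartment.

    ``dn_members`` must be a prefix of ``stages`` (the DN subsets precede
    every later stage); ``dn_weights``, when present, are the measured
    proportions of each DN subset and must sum to 1 within 1e-9.
    """

    system: str
    stages: tuple[str, ...]
    dn_members: tuple[str, ...] = ()
    dn_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(set(self.stages)) != len(self.stages):
            raise ValueError(f"duplicate stage names in {self.stages}")
        if tuple(self.stages[: len(self.dn_members)]) != tuple(self.dn_members):
            raise ValueError(
                f"dn_members {self.dn_members} must be a prefix of the stage ordering"
            )
        if self.dn_weights is not None:
            if set(self.dn_weights) != set(self.dn_members):
                raise ValueError("dn_weights keys must equal dn_members")
            total = sum(self.dn_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"dn_weights must sum to 1, got {total}")

    @classmethod
    def from_yaml(cls, path) -> "PopulationScheme":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls(
            system=spec["system"],
            stages=tuple(spec["stages"]),
            dn_members=tuple(spec.get("dn_members", ())),
            dn_weights=dict(spec["dn_weights"]) if spec.get("dn_weights") else None,
        )


# DN-subset proportions measured per system (fraction of the DN compartment)
MOUSE_THYMUS_SCHEME = PopulationScheme(
    system="M-THY",
    stages=("DN1", "DN2", "DN3", "ISP8", "DP early", "DP late", "SP8", "SP4"),
    dn_members=("DN1", "DN2", "DN3"),
    dn_weights={"DN1": 0.04, "DN2": 0.03, "DN3": 0.93},
)
MOUSE_ATO_SCHEME = PopulationScheme(
    system="M-ATO",
    stages=("DN1", "DN2", "DN3", "ISP8", "DP early", "DP late", "SP8", "SP4"),
    dn_members=("DN1", "DN2", "DN3"),
    dn_weights={"DN1": 0.01, "DN2": 0.01, "DN3": 0.98},
)
HUMAN_THYMUS_SCHEME = PopulationScheme(
    system="H-THY",
    stages=("Thy1", "Thy2", "Thy3", "ISP4", "DP early", "DP late", "SP8", "SP4"),
    dn_members=("Thy1", "Thy2", "Thy3"),
    dn_weights={"Thy1": 0.001, "Thy2": 0.599, "Thy3": 0.40},
)
HUMAN_ATO_SCHEME = PopulationScheme(
    system="H-ATO",
    stages=("Thy1", "Thy2", "Thy3", "ISP4", "DP early", "DP late", "SP8"),
    dn_members=("Thy1", "Thy2", "Thy3"),
    dn_weights={"Thy1": 0.001, "Thy2": 0.799, "Thy3": 0.20},
)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x population matrix tied to a :class:`PopulationScheme`.

    ``scale`` records the value scale ("vst" for variance-stabilized,
    "fpkm", or "zscore"); rows are unique genes and every column must be a
    stage of the scheme.
    """

    values: pd.DataFrame
    scheme: PopulationScheme
    scale: str = "vst"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup}")
        unknown = [c for c in self.values.columns if c not in self.scheme.stages]
        if unknown:
            raise ValueError(
                f"columns not in the {self.scheme.system} population scheme: {unknown}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def populations(self) -> list[str]:
        return list(self.values.columns)


def read_expression(path, scheme: PopulationScheme, scale: str = "vst") -> ExpressionMatrix:
    """Read a TSV (gene_id column + one column per population).

    Columns outside the scheme raise an error listing them; duplicate gene
    ids and non-numeric cells (reported with coordinates) are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise ValueError("expression table lacks a 'gene_id' column")
    df = df.set_index("gene_id")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gi, ci = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {df.iat[gi, ci]!r} at gene {df.index[gi]!r}, "
            f"column {df.columns[ci]!r}"
        )
    return ExpressionMatrix(values=numeric.astype(float), scheme=scheme, scale=scale)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def zscore_rows(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Standardize each gene row to mean 0, sample sd 1 across populations.

    Constant rows become all-zero and are returned in the second element
    rather than producing NaNs, so downstream pathway means stay defined.
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 populations")
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    constant = sd == 0.0
    safe_sd = sd.mask(constant, 1.0)
    z = df.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    zm = replace(matrix, values=z, scale="zscore")
    return zm, list(df.index[constant])


def composite_dn(matrix: ExpressionMatrix, weights: Mapping[str, float] | None = None) -> ExpressionMatrix:
    """Replace the DN subset columns by one weighted-average "DN" column.

    The DN value per gene is the convex combination sum_i w_i * x_i on the
    input scale; all other columns are unchanged and DN comes first.
    Weights default to the scheme's measured proportions and must cover
    exactly the DN members and sum to 1 within 1e-9.
    """
    scheme = matrix.scheme
    if not scheme.dn_members:
        raise ValueError(f"scheme {scheme.system} defines no DN members")
    w = dict(weights) if weights is not None else (
        dict(scheme.dn_weights) if scheme.dn_weights else None
    )
    if w is None:
        raise ValueError("no DN weights supplied and the scheme defines none")
    missing = [s for s in scheme.dn_members if s not in w]
    extra = [s for s in w if s not in scheme.dn_members]
    if missing or extra:
        raise ValueError(f"weights must cover exactly the DN members; missing {missing}, extra {extra}")
    total = sum(w.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"DN weights must sum to 1, got {total}")
    absent = [s for s in scheme.dn_members if s not in matrix.values.columns]
    if absent:
        raise ValueError(f"matrix lacks DN member columns: {absent}")

    dn = sum(matrix.values[s] * w[s] for s in scheme.dn_members)
    rest = [c for c in matrix.values.columns if c not in scheme.dn_members]
    out = pd.concat([dn.rename("DN"), matrix.values[rest]], axis=1)
    new_scheme = PopulationScheme(
        system=scheme.system,
        stages=("DN",) + tuple(s for s in scheme.stages if s not in scheme.dn_members),
        dn_members=("DN",),
        dn_weights=None,
    )
    return ExpressionMatrix(values=out, scheme=new_scheme, scale=matrix.scale)


@dataclass(frozen=True)
class GenePanel:
    """Named metabolic pathways mapped to gene-identifier lists.

    Genes are matched against a matrix case-insensitively so that mouse
    title-case and human upper-case symbols resolve to the same panel
    entry; a gene may belong to several pathways.
    """

    pathways: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        empty = [k for k, v in self.pathways.items() if not v]
        if empty:
            raise ValueError(f"empty gene list for pathways: {empty}")

    @classmethod
    def from_yaml(cls, path) -> "GenePanel":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls(pathways={str(k): tuple(str(g) for g in v) for k, v in spec.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in self.pathways.items()}, fh, sort_keys=False)

    def match(self, genes: Sequence[str]) -> dict[str, "PanelMatch"]:
        """Resolve each pathway's members against available gene ids."""
        lookup: dict[str, str] = {}
        for g in genes:
            lookup.setdefault(str(g).casefold(), str(g))
        out = {}
        for name, members in self.pathways.items():
            found, absent = [], []
            for m in members:
                hit = lookup.get(m.casefold())
                (found.append(hit) if hit is not None else absent.append(m))
            out[name] = PanelMatch(pathway=name, present=tuple(found), absent=tuple(absent))
        return out


@dataclass(frozen=True)
class PanelMatch:
    pathway: str
    present: tuple[str, ...]
    absent: tuple[str, ...]


#: A compact curated panel of pathway enzymes (human-style symbols; matching
#: is case-insensitive so mouse symbols resolve too).
DEFAULT_PANEL = GenePanel(
    pathways={
        "glycolysis": ("HK1", "HK2", "GAPDH", "PGK1", "PGAM1", "TPI1", "PFKL", "PFKM", "PFKP", "ENO1", "LDHA", "LDHB"),
        "tca": ("CS", "IDH3G", "PDHA1", "DLST", "SDHA", "FH", "MDH2"),
        "etc": ("NDUFA8", "NDUFV1", "SDHB", "UQCRC1", "COX5A", "ATP5F1A"),
        "purine_de_novo": ("PPAT", "GART", "ATIC", "PAICS"),
        "ppp": ("G6PD", "PGD", "TKT", "TALDO1"),
        "fao": ("CPT1A", "ACADVL", "HADHA", "ACOX1"),
        "regulators": ("MYC", "NOTCH1", "STAT3", "STAT5A", "NFE2L2", "HIF1A"),
    }
)


def pathway_trajectory(
    z_matrix: ExpressionMatrix, panel: GenePanel
) -> tuple[pd.DataFrame, dict[str, PanelMatch]]:
    """Per-pathway unweighted mean z-score per population.

    Returns (trajectory frame: pathway x population, match report). A
    pathway matching zero genes in the matrix is an error naming it;
    absent genes are reported in the match, never silently dropped.
    """
    matches = panel.match(z_matrix.genes)
    rows = {}
    for name, match in matches.items():
        if not match.present:
            raise ValueError(f"pathway {name!r} matches no genes in the matrix")
        rows[name] = z_matrix.values.loc[list(match.present)].mean(axis=0)
    traj = pd.DataFrame(rows).T
    traj.index.name = "pathway"
    return traj, matches


@dataclass(frozen=True)
class FilterResult:
    """Variable-gene filter outcome: the pass set plus a per-gene trace."""

    passed: frozenset[str]
    reasons: pd.DataFrame  # gene x predicate booleans, plus 'passed'


DE_COLUMNS = ("gene_id", "contrast", "fold_change", "adj_p", "max_fpkm", "max_cpm", "mappable_bp", "outlier")


def filter_variable_genes(
    de_table: pd.DataFrame,
    fc_min: float = 2.0,
    adj_p_max: float = 0.01,
    fpkm_min: float = 5.0,
    cpm_floor: float = 0.5,
    mappability_min_bp: float = 50.0,
) -> FilterResult:
    """Select variable genes from a precomputed differential-expression table.

    A gene passes iff, in at least one pairwise contrast, its fold change
    exceeds ``fc_min`` in either direction (fc > fc_min or fc < 1/fc_min)
    with BH-adjusted Wald p < ``adj_p_max``; and its peak expression reaches
    ``fpkm_min`` FPKM in some sample; and it clears the abundance
    (max CPM >= ``cpm_floor``), mappability (>= ``mappability_min_bp``) and
    count-outlier exclusions. The outlier flag is consumed as annotated by
    the upstream DE tool, not recomputed.
    """
    missing = [c for c in DE_COLUMNS if c not in de_table.columns]
    if missing:
        raise ValueError(f"DE table lacks columns: {missing}")
    if len(de_table) == 0:
        empty = pd.DataFrame(
            columns=["fc_and_p", "fpkm_ok", "cpm_ok", "mappable_ok", "not_outlier", "passed"]
        )
        return FilterResult(passed=frozenset(), reasons=empty)
    if (de_table["fold_change"] <= 0).any():
        raise ValueError("fold_change must be positive (linear scale)")

    fc = de_table["fold_change"].to_numpy(dtype=float)
    hit = ((fc > fc_min) | (fc < 1.0 / fc_min)) & (de_table["adj_p"].to_numpy(dtype=float) < adj_p_max)
    per_contrast = pd.DataFrame({"gene_id": de_table["gene_id"], "hit": hit})
    fc_and_p = per_contrast.groupby("gene_id", sort=True)["hit"].any()

    gene_level = de_table.drop_duplicates("gene_id").set_index("gene_id").loc[fc_and_p.index]
    reasons = pd.DataFrame(
        {
            "fc_and_p": fc_and_p,
            "fpkm_ok": gene_level["max_fpkm"].astype(float) >= fpkm_min,
            "cpm_ok": gene_level["max_cpm"].astype(float) >= cpm_floor,
            "mappable_ok": gene_level["mappable_bp"].astype(float) >= mappability_min_bp,
            "not_outlier": ~gene_level["outlier"].astype(bool),
        }
    )
    reasons["passed"] = reasons.all(axis=1)
    return FilterResult(
        passed=frozenset(reasons.index[reasons["passed"]]), reasons=reasons
    )


@dataclass(frozen=True)
class PCAResult:
    """Scores, loadings and variance fractions of standardized-input PCA."""

    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # features x components
    variance_fraction: np.ndarray
    dropped_features: tuple[str, ...] = ()


def pca_standardized(matrix: ExpressionMatrix | pd.DataFrame) -> PCAResult:
    """PCA of populations on gene features standardized to mean 0, sd 1.

    Genes are features, populations are observations. Constant genes carry
    no information after standardization and are dropped with a warning.
    Component sign follows a deterministic convention: the largest-magnitude
    loading of each component is made positive. Variance fractions are
    nonincreasing and sum to 1.
    """
    df = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 populations")
    X = df.to_numpy(dtype=float).T  # populations x genes
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = tuple(df.index[~keep])
    if dropped:
        warnings.warn(f"dropping constant features: {list(dropped)}", stacklevel=2)
        X = X[:, keep]
        if X.shape[1] == 0:
            raise ValueError("all features are constant")
    Xs = (X - X.mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    n_comp = min(Xs.shape[0] - 1, Xs.shape[1])
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    # sign convention: largest-|loading| entry of each component positive
    for k in range(n_comp):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{k + 1}" for k in range(n_comp)]
    scores = pd.DataFrame(u * s, index=df.columns, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=df.index[keep], columns=comp_names)
    return PCAResult(scores=scores, loadings=loadings, variance_fraction=frac, dropped_features=dropped)
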