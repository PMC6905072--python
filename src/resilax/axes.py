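"""Axis inference: PCA, confound-removing orthogonalization, orientation,
and projection.

An Axis is a unit loading vector over genes.  The developmental axis D is the
second principal component of unperturbed training samples; the raw
heat-stress component H-hat, inferred from heat-stressed training samples,
mixes the stress response with developmental drift (worms keep developing
while stressed), so the stress axis is defined by removing the developmental
direction:

    H = ( H-hat - (H-hat . D) D ) / || H-hat - (H-hat . D) D ||

The scalar overlap (H-hat . D) is retained as provenance.  The same recipe
yields the genetic axes: GD from genotype panels in control conditions, GH
from the same panel under heat stress orthogonalized against GD.  Projecting
a sample's standardized profile on an axis gives the scalar scores d, h, gd
or gh.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datasets import ExpressionDataset
from .preprocess import (
    DEFAULT_MIN_GENE_OVERLAP,
    Standardizer,
    apply_standardizer,
    fit_standardizer,
)

logger = logging.getLogger(__name__)

ORTHO_TOL = 1e-9          # orthogonality / unit-norm checks
DEGENERATE_RESIDUAL = 1e-8  # residual norm below which orthogonalization fails
ORIENTATION_MIN_RHO = 0.05  # association below this leaves the sign untouched


@dataclass
class Axis:
    """A unit gene-loading vector with its training standardizer.

    ``raw_loadings`` keeps the pre-orthogonalization principal component for
    provenance; ``confound_overlap`` is the scalar product between that raw
    component and the confound axis that was removed.
    """

    name: str
    loadings: np.ndarray
    gene_ids: pd.Index
    standardizer: Standardizer
    component_index: int = 0  # 1-based PCA rank the raw component came from
    variance_explained: float = float("nan")
    orientation_covariate: str | None = None
    confound_overlap: float | None = None
    raw_loadings: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids)
        if len(self.loadings) != len(self.gene_ids):
            raise ValueError("loadings and gene_ids must have equal length")
        norm = np.linalg.norm(self.loadings)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"axis loadings must be unit length (norm={norm})")
        if list(self.gene_ids) != list(self.standardizer.gene_ids):
            raise ValueError("axis gene_ids must match standardizer gene_ids")

    def dot(self, other: "Axis") -> float:
        """Scalar product with another axis over the shared gene set.

        The other axis is first re-expressed in *this* axis's standardized
        coordinates (loadings define a direction of expression change only
        relative to a per-gene scale), and both are re-normalized over the
        gene intersection.  Note the mild asymmetry: ``a.dot(b)`` evaluates
        in ``a``'s space.
        """
        a, b = _restrict_pair(self, other, rescale=True)
        return float(a @ b)

    def flipped(self) -> "Axis":
        raw = None if self.raw_loadings is None else -self.raw_loadings
        return replace(self, loadings=-self.loadings, raw_loadings=raw)


def _restrict_pair(a: Axis, b: Axis, rescale: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Loadings of two axes over their shared genes, unit-normalized.

    With ``rescale=True`` the second axis's loadings are converted into the
    first axis's standardized coordinates: a loading vector w fitted with
    per-gene scales s describes the expression displacement w * s, which in
    a space with scales s' reads w * s / s'.
    """
    shared = a.gene_ids[a.gene_ids.isin(b.gene_ids)]
    if len(shared) == 0:
        raise ValueError("axes share no genes")
    va = a.loadings[a.gene_ids.get_indexer(shared)]
    vb = b.loadings[b.gene_ids.get_indexer(shared)]
    if rescale:
        sd_a = a.standardizer.subset(shared).sd
        sd_b = b.standardizer.subset(shared).sd
        vb = vb * sd_b / sd_a
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("axis has zero norm on the shared gene set")
    return va / na, vb / nb


def fit_principal_axes(std_ds: ExpressionDataset, k: int) -> list[tuple[np.ndarray, float]]:
    """Principal axes of a standardized dataset via SVD.

    ``std_ds`` must already be centered and scaled per gene (see
    :func:`resilax.preprocess.apply_standardizer`).  Returns ``k`` pairs of
    (unit loading vector over genes, fraction of variance explained), ordered
    by decreasing variance.  Deterministic up to the usual PCA sign ambiguity,
    which is resolved later by :func:`orient_axis`.
    """
    X = std_ds.values.to_numpy().T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)  # exact centering for held-in PCA
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if k > max_rank:
        raise ValueError(f"k={k} exceeds the data rank ({max_rank})")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    return [(vt[i], float(frac[i])) for i in range(k)]


def select_component(
    components: list[tuple[np.ndarray, float]],
    covariate: np.ndarray,
    training_scores: np.ndarray,
    mode: str = "fixed_second",
) -> int:
    """Choose which principal component carries the variation of interest.

    ``training_scores`` has one row per component (projections of the
    training samples).  ``fixed_second`` returns component 2, the empirical
    choice for these data (the first component is typically technical
    array-to-array variation); ``max_association`` returns the component with
    the largest |Spearman rho| against the covariate and warns when the two
    disagree.  Returns a 1-based component index.
    """
    if len(components) < 2:
        raise ValueError("need at least 2 components to select from")
    if mode == "fixed_second":
        return 2
    if mode != "max_association":
        raise ValueError(f"unknown selection mode {mode!r}")
    covariate = np.asarray(covariate, dtype=float)
    if np.ptp(covariate) == 0:
        raise ValueError("covariate is constant; cannot rank components by association")
    rhos = []
    for scores in training_scores[: len(components)]:
        rho = stats.spearmanr(scores, covariate).statistic
        rhos.append(0.0 if np.isnan(rho) else abs(rho))
    best = int(np.argmax(rhos)) + 1
    if best != 2:
        logger.warning(
            "max_association selected component %d (|rho|=%.2f), not the usual component 2",
            best, rhos[best - 1],
        )
    return best


def orthogonalize(candidate: Axis, confound: Axis) -> Axis:
    """Remove the confound direction from a candidate axis (Gram-Schmidt step).

    Both axes are restricted to their shared genes; the confound direction is
    re-expressed in the candidate's standardized coordinates (the space in
    which the resulting axis projects samples) and both are re-normalized
    before the scalar product.  The residual is re-normalized to unit length
    so that projections stay comparable across axes.
    """
    shared = candidate.gene_ids[candidate.gene_ids.isin(confound.gene_ids)]
    v_cand, v_conf = _restrict_pair(candidate, confound, rescale=True)
    overlap = float(v_cand @ v_conf)
    residual = v_cand - overlap * v_conf
    norm = np.linalg.norm(residual)
    if norm < DEGENERATE_RESIDUAL:
        raise ValueError("axis degenerate after confound removal")
    logger.info(
        "orthogonalized %s against %s: overlap %.4f over %d shared genes",
        candidate.name, confound.name, overlap, len(shared),
    )
    return Axis(
        name=candidate.name,
        loadings=residual / norm,
        gene_ids=shared,
        standardizer=candidate.standardizer.subset(shared),
        component_index=candidate.component_index,
        variance_explained=candidate.variance_explained,
        confound_overlap=overlap,
        raw_loadings=v_cand,
    )


def project(ds: ExpressionDataset, axis: Axis,
            min_gene_overlap: float = DEFAULT_MIN_GENE_OVERLAP) -> pd.DataFrame:
    """Project raw samples onto an axis.

    The axis's own training standardizer is applied first, then each
    standardized profile is dotted with the loadings (restricted to the
    shared genes and re-normalized).  Returns a table with one row per
    sample: metadata columns plus ``score``; ``attrs['axis_name']`` records
    the axis.
    """
    std = apply_standardizer(ds, axis.standardizer, min_gene_overlap)
    w = axis.loadings[axis.gene_ids.get_indexer(std.gene_ids)]
    w = w / np.linalg.norm(w)
    scores = std.values.to_numpy().T @ w
    out = ds.samples.reset_index().loc[:, ["sample_id", "genotype", "treatment",
                                           "t_dev", "t_heat", "t_rec"]].copy()
    out["score"] = scores
    out.attrs["axis_name"] = axis.name
    return out


def orient_axis(axis: Axis, ds: ExpressionDataset, covariate: str) -> Axis:
    """Fix the PCA sign ambiguity against a biological covariate.

    ``covariate`` is a metadata column (``t_dev`` for D, ``t_heat`` for H) or
    ``"treatment_contrast"`` for the genetic axes, where the projection of
    heat-stressed samples must on average exceed that of control samples.
    Idempotent; if the association is negligible (|rho| < 0.05) the sign is
    left unchanged with a warning.
    """
    proj = project(ds, axis)
    if covariate == "treatment_contrast":
        sub = proj[proj["treatment"].isin(["control", "heat"])]
        if sub["treatment"].nunique() < 2:
            logger.warning("orientation contrast needs both control and heat samples; sign unchanged")
            return replace(axis, orientation_covariate=covariate)
        x = (sub["treatment"] == "heat").astype(float).to_numpy()
        y = sub["score"].to_numpy()
    else:
        x = proj[covariate].to_numpy(dtype=float)
        y = proj["score"].to_numpy()
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho) or abs(rho) < ORIENTATION_MIN_RHO:
        logger.warning(
            "axis %s shows no association with %s (rho=%.3f); sign left unchanged",
            axis.name, covariate, 0.0 if np.isnan(rho) else rho,
        )
        oriented = axis
    elif rho < 0:
        logger.info("flipping axis %s so projections increase with %s", axis.name, covariate)
        oriented = axis.flipped()
    else:
        oriented = axis
    return replace(oriented, orientation_covariate=covariate)


def derive_axis_pair(
    control_train: ExpressionDataset,
    stress_train: ExpressionDataset,
    names: tuple[str, str] = ("D", "H"),
    k: int | None = None,
    component_mode: str = "fixed_second",
    control_covariate: str = "t_dev",
    stress_covariate: str = "t_heat",
    orientation: str = "covariate",
) -> tuple[Axis, Axis]:
    """Full axis-inference pipeline for one (confound, stress) axis pair.

    Control training samples yield the confound axis (D or GD); stress
    training samples yield the raw stress component, which is orthogonalized
    against the confound and re-oriented.  ``orientation="covariate"`` orients
    each axis by its time covariate (D/H); ``orientation="contrast"`` orients
    both by the control-vs-heat mean contrast over the union of the two
    training sets (GD/GH, which have no time covariate).
    """

    def _infer(train: ExpressionDataset, tag: str, covariate_col: str) -> Axis:
        st = fit_standardizer(train, source_tag=tag)
        std = apply_standardizer(train, st)
        kk = k if k is not None else min(10, train.n_samples - 1, std.n_genes)
        comps = fit_principal_axes(std, kk)
        scores = np.stack([std.values.to_numpy().T @ v for v, _ in comps])
        cov = train.samples[covariate_col].to_numpy(dtype=float)
        idx = select_component(comps, cov, scores, mode=component_mode)
        v, frac = comps[idx - 1]
        return Axis(
            name=tag, loadings=v, gene_ids=std.gene_ids,
            standardizer=st.subset(std.gene_ids),
            component_index=idx, variance_explained=frac,
        )

    union = _concat(control_train, stress_train)
    orient_col_c = control_covariate if orientation == "covariate" else "treatment_contrast"
    orient_col_s = stress_covariate if orientation == "covariate" else "treatment_contrast"
    orient_ds_c = control_train if orientation == "covariate" else union
    orient_ds_s = stress_train if orientation == "covariate" else union

    confound = _infer(control_train, names[0], control_covariate
                      if orientation == "covariate" else "t_dev")
    confound = orient_axis(confound, orient_ds_c, orient_col_c)

    raw_stress = _infer(stress_train, names[1], stress_covariate
                        if orientation == "covariate" else "t_dev")
    stress = orthogonalize(raw_stress, confound)
    stress = orient_axis(stress, orient_ds_s, orient_col_s)
    return confound, stress


def _concat(a: ExpressionDataset, b: ExpressionDataset) -> ExpressionDataset:
    shared = a.gene_ids[a.gene_ids.isin(b.gene_ids)]
    b_ids = [s for s in b.sample_ids if s not in set(a.sample_ids)]
    values = pd.concat([a.values.loc[shared], b.values.loc[shared, b_ids]], axis=1)
    samples = pd.concat([a.samples, b.samples.loc[b_ids]])
    return ExpressionDataset(values, samples)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_axis(axis: Axis, out_dir) -> None:
    """Write an axis as loadings TSV + standardizer TSV + YAML sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"loading": axis.loadings}, index=axis.gene_ids.rename("gene_id"))
    if axis.raw_loadings is not None:
        df["raw_loading"] = axis.raw_loadings
    df.to_csv(out / "loadings.tsv", sep="\t", float_format="%.12g")
    axis.standardizer.to_frame().to_csv(out / "standardizer.tsv", sep="\t",
                                        float_format="%.12g")
    meta = {
        "name": axis.name,
        "component_index": int(axis.component_index),
        "variance_explained": float(axis.variance_explained),
        "orientation_covariate": axis.orientation_covariate,
        "confound_overlap": None if axis.confound_overlap is None
        else float(axis.confound_overlap),
        "standardizer_source": axis.standardizer.source_tag,
    }
    with open(out / "axis.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_axis(in_dir) -> Axis:
    src = Path(in_dir)
    df = pd.read_csv(src / "loadings.tsv", sep="\t", index_col=0)
    st_df = pd.read_csv(src / "standardizer.tsv", sep="\t", index_col=0)
    with open(src / "axis.yaml") as fh:
        meta = yaml.safe_load(fh)
    st = Standardizer.from_frame(st_df, meta.get("standardizer_source") or "")
    raw = df["raw_loading"].to_numpy() if "raw_loading" in df.columns else None
    return Axis(
        name=meta["name"],
        loadings=df["loading"].to_numpy(),
        gene_ids=df.index.astype(str),
        standardizer=st,
        component_index=meta["component_index"],
        variance_explained=meta["variance_explained"],
        orientation_covariate=meta.get("orientation_covariate"),
        confound_overlap=meta.get("confound_overlap"),
        raw_loadings=raw,
    )
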