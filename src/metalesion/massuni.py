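"""Voxel-wise lesion-deficit inference with permutation cluster-FWE control.

At every in-mask voxel the (residual-free, raw) metabolic intensity is
regressed on a single behavioural score of interest plus confounds (age,
handedness indicators, and the three background-activity sums).  Two
one-tailed t-tests are performed on the score slope — hypometabolism
accompanying impairment surfaces in the positive tail, paradoxical
hypometabolism-with-better-function in the negative tail — and suprathreshold
voxels (one-tailed p < 1e-4 by default) are grouped into 6-connected
clusters.  Family-wise error over clusters is controlled at 0.025 per tail
(the conventional 0.05 halved across the two one-tailed maps) by a
Freedman-Lane permutation scheme: the score is residualized on the
confounds, those residuals are permuted and re-entered, and the maximum
suprathreshold cluster size per permutation forms the null distribution of
cluster sizes.

Scores flagged higher-is-worse (e.g. HADS) are sign-flipped before design
construction so that a positive t-statistic uniformly means hypometabolism
accompanies impairment.

Usage::

    model = LesionDeficitModel(stack, scores, "verbal_iq", confounds)
    res = model.fit(n_perm=1000, seed=7)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .containers import CohortStack, GreyMatterMask, ScoreTable
from .preprocess import build_confound_matrix, _check_full_rank

__all__ = [
    "GLMDesign",
    "StatMap",
    "ClusterTable",
    "LesionDeficitModel",
    "LesionDeficitResults",
    "build_design",
    "fit_glm",
    "cluster_forming",
    "permutation_cluster_fwe",
    "peak_table",
]

T_SENTINEL = 1e4  # reported at perfect-fit voxels instead of infinity
_SIX_CONNECTED = ndimage.generate_binary_structure(3, 1)


@dataclass
class GLMDesign:
    """Design matrix with one score-of-interest column among confounds."""

    X: np.ndarray
    column_names: list[str]
    score_index: int
    score_name: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite entries")
        _check_full_rank(self.X, self.column_names)
        if self.df <= 0:
            raise ValueError("non-positive residual degrees of freedom")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def df(self) -> int:
        return self.X.shape[0] - self.X.shape[1]

    @property
    def contrast(self) -> np.ndarray:
        c = np.zeros(self.X.shape[1])
        c[self.score_index] = 1.0
        return c

    def confound_columns(self) -> np.ndarray:
        keep = [j for j in range(self.X.shape[1]) if j != self.score_index]
        return self.X[:, keep]

    def score_column(self) -> np.ndarray:
        return self.X[:, self.score_index]


@dataclass
class StatMap:
    """Per-voxel slope, standard error and t statistic for one tail."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    direction: str  # "positive" | "negative"
    undefined: np.ndarray
    perfect_fit: np.ndarray
    mask: GreyMatterMask

    def tail_t(self) -> np.ndarray:
        """t oriented so larger = more extreme in this map's tail."""
        return self.t if self.direction == "positive" else -self.t


@dataclass
class ClusterTable:
    """FWE-corrected suprathreshold clusters, sorted by corrected p."""

    table: pd.DataFrame  # direction, size, peak_i/j/k, peak x/y/z mm, peak_t, p_fwe...
    voxel_lists: list[np.ndarray]  # in-mask flat voxel indices per cluster
    n_perm: int
    alpha_per_tail: float
    p_uncorrected: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p_fwe"] < self.alpha_per_tail]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_design(
    scores: ScoreTable,
    score_name: str,
    confounds: pd.DataFrame,
    standardize_confounds: bool = True,
) -> GLMDesign:
    """Assemble [intercept, confounds..., score] with the score oriented so
    higher = better function (higher-is-worse instruments sign-flipped)."""
    if score_name not in scores.instruments:
        raise ValueError(f"unknown instrument {score_name!r}")
    y_score = scores.oriented(score_name)
    if not np.all(np.isfinite(y_score)):
        raise ValueError(
            f"score {score_name!r} has missing entries; impute before mapping"
        )
    Z, names = build_confound_matrix(confounds)
    if standardize_confounds:
        for j in range(1, Z.shape[1]):
            sd = Z[:, j].std(ddof=0)
            if sd > 0:
                Z[:, j] = (Z[:, j] - Z[:, j].mean()) / sd
    X = np.column_stack([Z, y_score])
    return GLMDesign(
        X=X,
        column_names=names + [score_name],
        score_index=X.shape[1] - 1,
        score_name=score_name,
    )


def _partial_stats(
    stack_data: np.ndarray, design: GLMDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Score-column beta/se/t by Frisch-Waugh partialling (equals full OLS)."""
    Z = design.confound_columns()
    g = design.score_column()
    Qz, _ = np.linalg.qr(Z)
    gr = g - Qz @ (Qz.T @ g)
    Yr = stack_data - Qz @ (Qz.T @ stack_data)
    df = design.df
    gss = float(gr @ gr)
    if gss <= 0:
        raise ValueError("score column is collinear with the confounds")
    num = Yr.T @ gr  # (V,)
    beta = num / gss
    yss = (Yr**2).sum(axis=0)
    rss = np.clip(yss - beta**2 * gss, 0.0, None)
    # a voxel whose residual variance is numerically nil relative to its raw
    # scale (constant, or exactly spanned by the confounds) is undefined
    raw_ss = (stack_data**2).sum(axis=0)
    undefined = yss <= 1e-20 * np.maximum(raw_ss, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / gss)
        t = beta / se
    perfect = (~undefined) & (rss <= 1e-12 * np.maximum(yss, 1e-300))
    t[perfect] = np.sign(beta[perfect]) * T_SENTINEL
    se[perfect] = np.abs(beta[perfect]) / T_SENTINEL
    t[undefined] = np.nan
    se[undefined] = np.nan
    beta = beta.copy()
    beta[undefined] = np.nan
    return beta, se, t, undefined, perfect, Yr


def fit_glm(stack: CohortStack, design: GLMDesign) -> tuple[StatMap, StatMap]:
    """Per-voxel OLS; returns positive- and negative-tail StatMaps sharing
    the same slopes with opposite directional tags."""
    if design.n != stack.n_subjects:
        raise ValueError("design row count does not match stack")
    beta, se, t, undefined, perfect, _ = _partial_stats(stack.data, design)
    common = dict(
        beta=beta, se=se, t=t, df=design.df,
        undefined=undefined, perfect_fit=perfect, mask=stack.mask,
    )
    return (
        StatMap(direction="positive", **common),
        StatMap(direction="negative", **common),
    )


def cluster_forming(statmap: StatMap, p_uncorrected: float) -> np.ndarray:
    """Label suprathreshold voxels into 6-connected components.

    The cluster-forming threshold is the one-tailed Student-t quantile at
    ``1 - p_uncorrected`` with the design's residual df.  Returns an integer
    label grid (0 = subthreshold / out of mask).
    """
    if not 0.0 < p_uncorrected < 1.0:
        raise ValueError("p_uncorrected must lie in (0, 1)")
    t_star = stats.t.ppf(1.0 - p_uncorrected, statmap.df)
    tail = statmap.tail_t()
    supra = np.zeros(statmap.mask.n_voxels, dtype=bool)
    ok = ~statmap.undefined
    supra[ok] = tail[ok] >= t_star
    grid = statmap.mask.unflatten(supra.astype(float), fill=0.0) > 0.5
    labels, _ = ndimage.label(grid, structure=_SIX_CONNECTED)
    return labels


def _max_cluster_size(supra_flat: np.ndarray, mask: GreyMatterMask) -> int:
    if not supra_flat.any():
        return 0
    grid = mask.unflatten(supra_flat.astype(float), fill=0.0) > 0.5
    labels, nlab = ndimage.label(grid, structure=_SIX_CONNECTED)
    if nlab == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _observed_clusters(
    statmap: StatMap, labels: np.ndarray
) -> tuple[list[np.ndarray], list[int]]:
    """Cluster in-mask flat-voxel index lists and sizes from a label grid."""
    mask = statmap.mask
    labels_flat = labels.ravel()[mask.indices]
    out_idx, out_size = [], []
    for lab in range(1, labels.max() + 1):
        members = np.flatnonzero(labels_flat == lab)
        if members.size:
            out_idx.append(members)
            out_size.append(int(members.size))
    return out_idx, out_size


def permutation_cluster_fwe(
    stack: CohortStack,
    design: GLMDesign,
    p_uncorrected: float = 1e-4,
    alpha_per_tail: float = 0.025,
    n_perm: int = 1000,
    seed: int = 0,
    label_volume: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
) -> ClusterTable:
    """Freedman-Lane max-cluster-size permutation FWE over both tails.

    The score is residualized on the confounds; the residuals are permuted,
    re-residualized, and the score-slope t map recomputed for each
    permutation (all permutations evaluated in one batched linear-algebra
    pass).  Each tail's null is the distribution of its maximum
    suprathreshold cluster size; the corrected p of an observed cluster of
    size ``s`` is ``(1 + #{perm max >= s}) / (n_perm + 1)``.  Perfect-fit
    voxels carry a capped t sentinel and are excluded from permutation
    maxima.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for usable p resolution")
    beta, se, t, undefined, perfect, Yr = _partial_stats(stack.data, design)
    df = design.df
    pos_map, neg_map = fit_glm(stack, design)

    t_star = stats.t.ppf(1.0 - p_uncorrected, df)
    pos_labels = cluster_forming(pos_map, p_uncorrected)
    neg_labels = cluster_forming(neg_map, p_uncorrected)

    # batched permutation null
    Z = design.confound_columns()
    g = design.score_column()
    Qz, _ = np.linalg.qr(Z)
    gr = g - Qz @ (Qz.T @ g)
    rng = np.random.default_rng(seed)
    n = design.n
    G = np.empty((n, n_perm))
    for b in range(n_perm):
        G[:, b] = gr[rng.permutation(n)]
    G -= Qz @ (Qz.T @ G)  # re-residualize after permutation
    gnorm = np.sqrt((G**2).sum(axis=0))
    gnorm[gnorm == 0] = np.inf
    ynorm = np.sqrt((Yr**2).sum(axis=0))
    y_ok = ynorm > 1e-150
    ynorm_safe = np.where(y_ok, ynorm, np.inf)
    R = (Yr.T @ G) / ynorm_safe[:, None] / gnorm[None, :]  # (V, n_perm) corr
    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt(df) / np.sqrt(np.clip(1.0 - R**2, 1e-12, None))
    T[~y_ok, :] = 0.0
    # exclude perfect permutation fits from the null maxima
    T[np.abs(R) > 1.0 - 1e-12] = 0.0

    max_pos = np.zeros(n_perm, dtype=int)
    max_neg = np.zeros(n_perm, dtype=int)
    mask = stack.mask
    pos_any = np.flatnonzero((T >= t_star).any(axis=0))
    neg_any = np.flatnonzero((T <= -t_star).any(axis=0))
    for b in pos_any:
        max_pos[b] = _max_cluster_size(T[:, b] >= t_star, mask)
    for b in neg_any:
        max_neg[b] = _max_cluster_size(T[:, b] <= -t_star, mask)

    rows = []
    voxel_lists: list[np.ndarray] = []
    for statmap, labels, null_max in (
        (pos_map, pos_labels, max_pos),
        (neg_map, neg_labels, max_neg),
    ):
        clusters, sizes = _observed_clusters(statmap, labels)
        tail = statmap.tail_t()
        for members, size in zip(clusters, sizes):
            p_fwe = float((1 + int((null_max >= size).sum())) / (n_perm + 1))
            p_unc_cluster = float(np.mean(null_max >= size))
            rows.append(
                {
                    "direction": statmap.direction,
                    "size": size,
                    "p_fwe": p_fwe,
                    "p_uncorrected_cluster": p_unc_cluster,
                    "_members": members,
                    "_tail_t": tail[members],
                }
            )
            voxel_lists.append(members)
    table = _assemble_cluster_frame(rows, mask, label_volume, label_names)
    order = np.argsort(table["p_fwe"].to_numpy(), kind="stable") if len(table) else []
    table = table.iloc[order].reset_index(drop=True)
    voxel_lists = [voxel_lists[i] for i in order]
    return ClusterTable(
        table=table,
        voxel_lists=voxel_lists,
        n_perm=n_perm,
        alpha_per_tail=alpha_per_tail,
        p_uncorrected=p_uncorrected,
    )


def _assemble_cluster_frame(
    rows: list[dict],
    mask: GreyMatterMask,
    label_volume: np.ndarray | None,
    label_names: dict[int, str] | None,
) -> pd.DataFrame:
    if label_volume is not None:
        label_volume = np.asarray(label_volume)
        if label_volume.shape != mask.grid.shape:
            raise ValueError("label volume grid does not match the mask")
    coords = mask.coordinates()
    world = mask.world_coordinates()
    out = []
    for row in rows:
        members = row.pop("_members")
        tail_t = row.pop("_tail_t")
        finite = np.where(np.isfinite(tail_t), tail_t, -np.inf)
        # tie on peak t -> lowest in-mask linear index wins (argmax is first)
        peak_local = int(np.argmax(finite))
        peak = members[peak_local]
        row["peak_i"], row["peak_j"], row["peak_k"] = (int(v) for v in coords[peak])
        row["peak_x_mm"], row["peak_y_mm"], row["peak_z_mm"] = (
            float(v) for v in world[peak]
        )
        row["peak_t"] = float(tail_t[peak_local])
        if label_volume is not None:
            lab = int(label_volume[tuple(coords[peak])])
            row["label"] = (label_names or {}).get(lab, str(lab))
        out.append(row)
    columns = [
        "direction", "size", "peak_i", "peak_j", "peak_k",
        "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_t",
        "p_uncorrected_cluster", "p_fwe",
    ]
    if label_volume is not None:
        columns.append("label")
    return pd.DataFrame(out, columns=columns if out else columns)


def peak_table(
    clusters: ClusterTable,
    statmap: StatMap | None = None,
    label_volume: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
) -> ClusterTable:
    """Re-annotate a cluster table with peak coordinates and region labels.

    Peaks are the maximum tail-t voxels (ties broken toward the lowest
    in-mask linear index); coordinates are reported in mm through the mask
    affine.  ``label_volume`` (grid-aligned integer labels) adds a region
    name per peak.
    """
    if statmap is None:
        return clusters
    mask = statmap.mask
    rows = []
    for i in range(len(clusters.table)):
        members = clusters.voxel_lists[i]
        rows.append(
            {
                "direction": clusters.table.iloc[i]["direction"],
                "size": int(clusters.table.iloc[i]["size"]),
                "p_fwe": float(clusters.table.iloc[i]["p_fwe"]),
                "p_uncorrected_cluster": float(
                    clusters.table.iloc[i]["p_uncorrected_cluster"]
                ),
                "_members": members,
                "_tail_t": statmap.tail_t()[members]
                if clusters.table.iloc[i]["direction"] == statmap.direction
                else -statmap.tail_t()[members],
            }
        )
    table = _assemble_cluster_frame(rows, mask, label_volume, label_names)
    return ClusterTable(
        table=table,
        voxel_lists=list(clusters.voxel_lists),
        n_perm=clusters.n_perm,
        alpha_per_tail=clusters.alpha_per_tail,
        p_uncorrected=clusters.p_uncorrected,
    )


class LesionDeficitModel:
    """Mass-univariate lesion-deficit model for one behavioural score.

    Parameters
    ----------
    stack : CohortStack
        Raw (non-residualized) intensities; confounds enter the design.
    scores : ScoreTable
        Complete (imputed) battery.
    score_name : str
        Instrument to map.
    confounds : DataFrame
        Age, handedness, and background sums (see
        :func:`metalesion.preprocess.build_confound_matrix`).
    """

    def __init__(
        self,
        stack: CohortStack,
        scores: ScoreTable,
        score_name: str,
        confounds: pd.DataFrame,
    ) -> None:
        self.stack = stack
        self.scores = scores
        self.score_name = score_name
        self.confounds = confounds
        self.design = build_design(scores, score_name, confounds)

    def fit(
        self,
        p_uncorrected: float = 1e-4,
        alpha_per_tail: float = 0.025,
        n_perm: int = 1000,
        seed: int = 0,
        label_volume: np.ndarray | None = None,
        label_names: dict[int, str] | None = None,
    ) -> "LesionDeficitResults":
        pos, neg = fit_glm(self.stack, self.design)
        clusters = permutation_cluster_fwe(
            self.stack,
            self.design,
            p_uncorrected=p_uncorrected,
            alpha_per_tail=alpha_per_tail,
            n_perm=n_perm,
            seed=seed,
            label_volume=label_volume,
            label_names=label_names,
        )
        return LesionDeficitResults(
            model=self, positive=pos, negative=neg, clusters=clusters
        )


@dataclass
class LesionDeficitResults:
    """StatMaps for both tails plus the FWE-corrected cluster table."""

    model: LesionDeficitModel
    positive: StatMap
    negative: StatMap
    clusters: ClusterTable

    def summary(self) -> str:
        d = self.model.design
        sig = self.clusters.significant()
        lines = [
            f"Lesion-deficit map: {self.model.score_name}",
            f"  n subjects: {d.n}   design columns: {len(d.column_names)}   df: {d.df}",
            f"  cluster-forming p (one-tailed): {self.clusters.p_uncorrected:g}"
            f"   FWE alpha per tail: {self.clusters.alpha_per_tail:g}"
            f"   permutations: {self.clusters.n_perm}",
            f"  clusters: {len(self.clusters.table)} total, {len(sig)} significant",
        ]
        if len(self.clusters.table):
            lines.append(
                self.clusters.table.drop(
                    columns=["p_uncorrected_cluster"]
                ).to_string(index=False)
            )
        return "\n".join(lines)
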