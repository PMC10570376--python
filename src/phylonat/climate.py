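"""Climate ordination and climatic-suitability scoring.

Two roles:

1. A PCA over the 19 bioclim variables (per grid cell, after optional
   per-variable normalizing transforms and centering/scaling).  Axis 1
   (``PC_Temp``) is sign-fixed so warm regions score high — its loading on
   mean annual temperature (bio1) is positive — and axis 2 (``PC_Prec``)
   so humid regions score high (positive loading on annual precipitation,
   bio12).  Region scores are unweighted means over the region's cells.

2. A climate-envelope suitability model per species over six bioclim
   variables (mean diurnal range bio2, temperature seasonality bio4, max
   temperature of warmest month bio5, precipitation seasonality bio15,
   precipitation of wettest quarter bio16, precipitation of driest
   quarter bio17).  The suitability score of a cell is
   ``exp(-0.5 * squared Mahalanobis distance)`` to the training-presence
   mean/covariance, an envelope analogue of presence-only SDM scoring that
   also accepts externally computed scores.  Models are trained on a
   seeded 80/20 presence split, retained when test AUC > 0.7, and
   thresholded at maximum training sensitivity + specificity; a region is
   suitable when at least one of its cells scores at or above the
   threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "BIOCLIM_VARS",
    "SDM_VARS",
    "TransformSpec",
    "transform_variable",
    "PcaModel",
    "fit_climate_pca",
    "region_pc_scores",
    "region_scores_frame",
    "SuitabilityModel",
    "fit_envelope_model",
    "evaluate_auc",
    "max_sss_threshold",
    "suitable_regions",
    "suitability_table",
    "TooFewOccurrences",
]

BIOCLIM_VARS = [f"bio{i}" for i in range(1, 20)]
#: the six variables used for suitability models
SDM_VARS = ["bio2", "bio4", "bio5", "bio15", "bio16", "bio17"]


class TooFewOccurrences(ValueError):
    """Species has too few presence cells for a suitability model."""


@dataclass
class TransformSpec:
    """A monotone normalizing transform with fitted parameters.

    ``name`` is one of ``identity``, ``log1p_shift``, ``sqrt_shift`` or
    ``power`` (Yeo–Johnson with a data-fitted exponent).  Parameters are
    fitted on first use and recorded for reuse on new data.
    """

    name: str = "power"
    params: dict = field(default_factory=dict)

    def fitted(self) -> bool:
        return self.name == "identity" or bool(self.params)


def transform_variable(
    values, spec: TransformSpec, variable: str = "<unnamed>"
) -> np.ndarray:
    """Apply (fitting if necessary) a normalizing transform to a vector."""
    x = np.asarray(values, dtype=float)
    if spec.name == "identity":
        out = x
    elif spec.name in ("log1p_shift", "sqrt_shift"):
        if "shift" not in spec.params:
            spec.params["shift"] = float(max(0.0, -x.min()))
        shifted = x + spec.params["shift"]
        out = np.log1p(shifted) if spec.name == "log1p_shift" else np.sqrt(
            shifted
        )
    elif spec.name == "power":
        if "lmbda" not in spec.params:
            _, lmbda = stats.yeojohnson(x)
            spec.params["lmbda"] = float(lmbda)
        out = stats.yeojohnson(x, lmbda=spec.params["lmbda"])
    else:
        raise ValueError(f"unknown transform {spec.name!r}")
    if not np.all(np.isfinite(out)):
        raise ValueError(
            f"transform {spec.name!r} produced non-finite values for "
            f"variable {variable!r}"
        )
    return out


@dataclass
class PcaModel:
    """Fitted climate PCA: transforms, scaling constants and loadings."""

    variables: list[str]
    transforms: dict[str, TransformSpec]
    means: np.ndarray
    sds: np.ndarray
    components: np.ndarray  # (n_axes, n_vars), orthonormal rows
    explained: np.ndarray   # explained-variance fractions, non-increasing
    mode: str = "cell"

    def standardize(self, frame: pd.DataFrame) -> np.ndarray:
        cols = []
        for j, var in enumerate(self.variables):
            y = transform_variable(
                frame[var].to_numpy(), self.transforms[var], var
            )
            cols.append((y - self.means[j]) / self.sds[j])
        return np.column_stack(cols)

    def scores(self, frame: pd.DataFrame) -> np.ndarray:
        """Axis scores for each row of a bioclim table."""
        return self.standardize(frame) @ self.components.T


def fit_climate_pca(
    grid: pd.DataFrame,
    transforms: dict[str, TransformSpec] | None = None,
    variables: list[str] | None = None,
    mode: str = "cell",
    n_axes: int | None = None,
) -> PcaModel:
    """PCA of the bioclim variables across grid cells.

    ``mode='cell'`` (default) fits on individual cells; ``mode='region'``
    fits on per-region variable means (the sensitivity variant).  Each
    variable is passed through its normalizing transform (default: fitted
    Yeo–Johnson power transform), centered, and scaled to unit variance.
    Axis signs are fixed by the bio1/bio12 loading conventions.
    """
    variables = variables or BIOCLIM_VARS
    if mode not in ("cell", "region"):
        raise ValueError("mode must be 'cell' or 'region'")
    data = (
        grid if mode == "cell"
        else grid.groupby("region_id", as_index=False)[variables].mean()
    )
    if len(data) < 20:
        raise ValueError("need at least 20 rows (cells) to fit the PCA")
    transforms = {
        var: (transforms or {}).get(var, TransformSpec("power"))
        for var in variables
    }
    cols, means, sds = [], [], []
    for var in variables:
        y = transform_variable(data[var].to_numpy(), transforms[var], var)
        sd = y.std(ddof=0)
        if sd == 0:
            raise ValueError(
                f"variable {var!r} has zero variance after transform"
            )
        means.append(y.mean())
        sds.append(sd)
        cols.append((y - y.mean()) / sd)
    X = np.column_stack(cols)
    n_axes = n_axes or min(X.shape)
    pca = PCA(n_components=n_axes, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    explained = pca.explained_variance_ratio_.copy()

    # sign conventions: warm → high axis 1, humid → high axis 2
    for axis, anchor in ((0, "bio1"), (1, "bio12")):
        if axis < components.shape[0] and anchor in variables:
            j = variables.index(anchor)
            if components[axis, j] < 0:
                components[axis] *= -1
    return PcaModel(
        variables=variables,
        transforms=transforms,
        means=np.array(means),
        sds=np.array(sds),
        components=components,
        explained=explained,
        mode=mode,
    )


def region_pc_scores(
    pca: PcaModel, grid: pd.DataFrame, region_id: str
) -> tuple[float, float]:
    """(PC_Temp, PC_Prec) for a region: mean of its cell-level scores."""
    cells = grid[grid["region_id"] == region_id]
    if cells.empty:
        raise KeyError(f"region {region_id!r} has no cells in the grid")
    sc = pca.scores(cells).mean(axis=0)
    return float(sc[0]), float(sc[1])


def region_scores_frame(pca: PcaModel, grid: pd.DataFrame) -> pd.DataFrame:
    """PC_Temp / PC_Prec for every region in the grid."""
    scores = pca.scores(grid)
    df = pd.DataFrame(
        {
            "region_id": grid["region_id"].to_numpy(),
            "pc_temp": scores[:, 0],
            "pc_prec": scores[:, 1],
        }
    )
    return (
        df.groupby("region_id", as_index=False)[["pc_temp", "pc_prec"]]
        .mean()
        .sort_values("region_id")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------
# suitability models
# ---------------------------------------------------------------------


def evaluate_auc(scores_pos, scores_neg) -> float:
    """Probability a random positive outscores a random negative.

    Rank-sum (Mann–Whitney) formulation with ties counted one half.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score vectors must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def max_sss_threshold(scores, labels) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the unique observed scores, prediction rule
    ``score >= threshold → present``; ties break toward the largest
    threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    pos, neg = s[y], s[~y]
    candidates = np.unique(s)
    sens = (pos[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (neg[None, :] < candidates[:, None]).mean(axis=1)
    total = sens + spec
    best = total.max()
    return float(candidates[total >= best - 1e-12].max())


@dataclass
class SuitabilityModel:
    """Climate envelope for one species over the six SDM variables."""

    species: str
    variables: list[str]
    mean: np.ndarray
    cov: np.ndarray
    icov: np.ndarray
    ridge: float
    auc_test: float
    threshold: float
    retained: bool
    n_presence: int

    def score(self, cells: pd.DataFrame) -> np.ndarray:
        """Suitability in (0, 1]: exp(−½ · squared Mahalanobis distance)."""
        X = cells[self.variables].to_numpy(dtype=float) - self.mean
        d2 = np.einsum("ij,jk,ik->i", X, self.icov, X)
        return np.exp(-0.5 * np.maximum(d2, 0.0))


def _regularized_inverse(cov: np.ndarray) -> tuple[np.ndarray, float]:
    eps = 0.0
    scale = np.trace(cov) / cov.shape[0]
    for trial in (0.0, 1e-8, 1e-6, 1e-4, 1e-2):
        eps = trial * scale
        try:
            icov = np.linalg.inv(cov + eps * np.eye(cov.shape[0]))
            # reject wildly ill-conditioned solutions
            if np.all(np.isfinite(icov)):
                return icov, eps
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("covariance could not be inverted")


def fit_envelope_model(
    presence_cells: pd.DataFrame,
    background_cells: pd.DataFrame,
    species: str = "<unnamed>",
    seed: int = 0,
    variables: list[str] | None = None,
    min_presences: int = 16,
) -> SuitabilityModel:
    """Fit and evaluate the climate envelope for one species.

    Requires more than 15 presence cells; 80% of presences train the
    envelope (mean and covariance of the six variables), the held-out 20%
    are scored against the background for the test AUC.  The max-SSS
    threshold is taken on the training presences.  A singular training
    covariance is ridge-regularized (the epsilon is recorded on the
    model).
    """
    variables = variables or SDM_VARS
    n = len(presence_cells)
    if n < min_presences:
        raise TooFewOccurrences(
            f"species {species!r}: {n} presence cells "
            f"(needs at least {min_presences})"
        )
    if len(background_cells) < n:
        raise ValueError("background must be at least as large as presences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, int(round(0.2 * n)))
    test_idx, train_idx = order[:n_test], order[n_test:]
    P = presence_cells[variables].to_numpy(dtype=float)
    train, test = P[train_idx], P[test_idx]

    mean = train.mean(axis=0)
    cov = np.cov(train, rowvar=False)
    icov, eps = _regularized_inverse(cov)
    model = SuitabilityModel(
        species=species, variables=list(variables), mean=mean, cov=cov,
        icov=icov, ridge=eps, auc_test=np.nan, threshold=np.nan,
        retained=False, n_presence=n,
    )
    bg_scores = model.score(background_cells)
    test_scores = model.score(
        pd.DataFrame(test, columns=variables)
    )
    train_scores = model.score(
        pd.DataFrame(train, columns=variables)
    )
    model.auc_test = evaluate_auc(test_scores, bg_scores)
    model.threshold = max_sss_threshold(
        np.concatenate([train_scores, bg_scores]),
        np.concatenate(
            [np.ones(train_scores.size, bool), np.zeros(bg_scores.size, bool)]
        ),
    )
    model.retained = bool(model.auc_test > 0.7)
    return model


def suitable_regions(
    model: SuitabilityModel, grid: pd.DataFrame
) -> set[str]:
    """Regions with at least one cell at or above the model threshold."""
    if not model.retained:
        raise ValueError(
            f"model for {model.species!r} was not retained (test AUC "
            f"{model.auc_test:.3f} <= 0.7)"
        )
    scores = model.score(grid)
    ok = pd.Series(scores >= model.threshold).groupby(
        grid["region_id"].to_numpy()
    ).any()
    return set(ok.index[ok])


def suitability_table(
    occurrences: pd.DataFrame,
    grid: pd.DataFrame,
    species_list=None,
    seed: int = 0,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Suitable-region sets for many species at once.

    ``occurrences`` has columns species, cell_id; presence cells are the
    matching grid rows and the remaining (non-presence) cells serve as
    background.  Species with too few presences, with fewer background
    than presence cells, or with a non-retained model get no entry.
    Returns the species → region-id-set mapping and a per-species report
    (n_presence, auc_test, threshold, status).
    """
    out: dict[str, set[str]] = {}
    report_rows = []
    cells_by_species = occurrences.groupby("species")["cell_id"]
    targets = (
        sorted(species_list) if species_list is not None
        else sorted(cells_by_species.groups)
    )
    grid_by_cell = grid.set_index("cell_id", drop=False)
    for sp in targets:
        if sp not in cells_by_species.groups:
            report_rows.append((sp, 0, np.nan, np.nan, "no_occurrences"))
            continue
        cell_ids = set(cells_by_species.get_group(sp).unique())
        presence = grid_by_cell.loc[
            [c for c in grid_by_cell.index if c in cell_ids]
        ]
        background = grid[~grid["cell_id"].isin(cell_ids)]
        try:
            model = fit_envelope_model(
                presence, background, species=sp,
                seed=_species_seed(seed, sp),
            )
        except TooFewOccurrences:
            report_rows.append(
                (sp, len(presence), np.nan, np.nan, "too_few_occurrences")
            )
            continue
        except ValueError:
            report_rows.append(
                (sp, len(presence), np.nan, np.nan,
                 "background_smaller_than_presences")
            )
            continue
        if not model.retained:
            report_rows.append(
                (sp, len(presence), model.auc_test, model.threshold,
                 "low_auc")
            )
            continue
        out[sp] = suitable_regions(model, grid)
        report_rows.append(
            (sp, len(presence), model.auc_test, model.threshold, "retained")
        )
    report = pd.DataFrame(
        report_rows,
        columns=["species", "n_presence", "auc_test", "threshold", "status"],
    )
    return out, report


def _species_seed(seed: int, species: str) -> int:
    import hashlib

    digest = hashlib.sha256(f"{seed}:{species}".encode()).digest()
    return int.from_bytes(digest[:4], "little")
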