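"""Presence/pseudoabsence ensemble modeling.

For each species: draw pseudoabsence replicates uniformly over eligible sea
cells, build the design matrix, make repeated stratified 75/25 splits (five
evaluation folds plus one full-data pseudo-fold), fit every learner on every
(pseudoabsence replicate × fold), evaluate TSS and ROC AUC on the held-out
quarter, and combine the members passing TSS > tss_min into a TSS-weighted
committee with its own TSS-optimal binarization threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    EnsembleEmptyError,
    InsufficientDomainError,
    StratificationError,
)
from .grid import EnvStack, RasterLayer
from .metrics import optimize_threshold, roc_auc
from .models import FittedModel, fit_model
from .occurrences import OccurrenceSet


@dataclass
class PseudoAbsenceSet:
    """One replicate of background points, one per sampled sea cell."""

    rep_index: int
    points: pd.DataFrame  # columns lon, lat, row, col
    n: int


def sample_pseudoabsences(
    stack: EnvStack,
    occ: OccurrenceSet,
    n: int = 5000,
    n_reps: int = 3,
    seed: int = 0,
) -> list[PseudoAbsenceSet]:
    """Uniform pseudoabsence replicates over valid cells excluding presences.

    Each replicate samples ``n`` distinct cells without replacement; points
    are placed at cell centres.  Raises if fewer than ``n`` cells are
    eligible — sampling with replacement is never silently substituted.
    """
    spec = stack.spec
    eligible = ~stack.combined_mask()
    rows, cols, inside = spec.cells_of(occ.lons, occ.lats)
    eligible[rows[inside], cols[inside]] = False
    flat = np.flatnonzero(eligible.ravel())
    if flat.size < n:
        raise InsufficientDomainError(
            f"{flat.size} eligible cells but {n} pseudoabsences requested"
        )
    out = []
    for rep, child in enumerate(np.random.SeedSequence(seed).spawn(n_reps), start=1):
        rng = np.random.default_rng(child)
        pick = rng.choice(flat, size=n, replace=False)
        r, c = np.unravel_index(pick, spec.shape)
        lon = spec.lon_min + (c + 0.5) * spec.cell_size
        lat = spec.lat_max - (r + 0.5) * spec.cell_size
        out.append(PseudoAbsenceSet(
            rep_index=rep,
            points=pd.DataFrame({"lon": lon, "lat": lat, "row": r, "col": c}),
            n=n,
        ))
    return out


def build_training_table(
    stack: EnvStack,
    occ: OccurrenceSet,
    pa: PseudoAbsenceSet,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Design matrix: presence rows (label 1) then pseudoabsence rows (0).

    Columns: lon, lat, label, then one column per environmental variable
    sampled at the containing cell.  Presence records falling on nodata cells
    are dropped (no missing values allowed downstream).
    """
    variables = variables if variables is not None else stack.names
    missing = [v for v in variables if v not in stack]
    if missing:
        raise ConfigurationError(f"stack lacks variables {missing}")
    spec = stack.spec
    rows, cols, inside = spec.cells_of(occ.lons, occ.lats)
    valid = inside.copy()
    mask = stack.combined_mask(variables)
    valid[inside] &= ~mask[rows[inside], cols[inside]]
    pres = stack.table(rows[valid], cols[valid], variables)
    pres.insert(0, "lat", occ.lats[valid])
    pres.insert(0, "lon", occ.lons[valid])
    pres.insert(2, "label", 1)
    pa_rows = pa.points["row"].to_numpy()
    pa_cols = pa.points["col"].to_numpy()
    absn = stack.table(pa_rows, pa_cols, variables)
    absn.insert(0, "lat", pa.points["lat"].to_numpy())
    absn.insert(0, "lon", pa.points["lon"].to_numpy())
    absn.insert(2, "label", 0)
    return pd.concat([pres, absn], ignore_index=True)


def split_train_test(
    labels: np.ndarray,
    train_fraction: float = 0.75,
    n_folds: int = 5,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Repeated stratified splits plus one full-data pseudo-fold.

    Returns ``n_folds + 1`` pairs of (train_idx, test_idx).  The first
    ``n_folds`` are independent stratified ``train_fraction``/(1 − fraction)
    splits (class proportions preserved to within one row); the final pair
    uses every row for training and none for testing.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise StratificationError("both classes required to split")
    for c in classes:
        if (labels == c).sum() < n_folds:
            raise StratificationError(
                f"class {c} has fewer than n_folds={n_folds} rows"
            )
    folds = []
    for child in np.random.SeedSequence(seed).spawn(n_folds):
        rng = np.random.default_rng(child)
        train_mask = np.zeros(labels.size, dtype=bool)
        for c in classes:
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            n_train = int(round(train_fraction * idx.size))
            train_mask[idx[:n_train]] = True
        folds.append((np.flatnonzero(train_mask), np.flatnonzero(~train_mask)))
    folds.append((np.arange(labels.size), np.array([], dtype=int)))
    return folds


@dataclass(frozen=True)
class EvaluationRecord:
    """Held-out skill of one (algorithm × PA replicate × fold) member."""

    algorithm_id: str
    pa_rep: int
    fold: int
    tss: float
    roc_auc: float
    optimal_threshold: float


@dataclass
class EnsembleMember:
    model: FittedModel
    record: EvaluationRecord


@dataclass
class EnsembleModel:
    """TSS-weighted committee of high-skill members.

    Members passed TSS > ``tss_min`` on their held-out split; weights are
    proportional to member TSS and sum to 1.  ``threshold`` is the
    TSS-optimal cutoff of the weighted-average score on the pooled held-out
    rows, used to binarize suitability maps.
    """

    members: list[EnsembleMember]
    weights: np.ndarray
    tss_min: float
    threshold: float
    variables: list[str] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(X))
        for w, m in zip(self.weights, self.members):
            out += w * m.model.predict(X)
        return out


def evaluate_members(
    table: pd.DataFrame,
    folds: list[tuple[np.ndarray, np.ndarray]],
    pa_rep: int,
    algorithms: tuple[str, ...],
    variables: list[str],
    seed: int = 0,
) -> tuple[list[EnsembleMember], list[FittedModel]]:
    """Fit and evaluate every (algorithm × fold) member for one PA replicate.

    Returns (evaluated members from the held-out folds, full-data fits from
    the final pseudo-fold).
    """
    y = table["label"].to_numpy()
    X = table[variables]
    members: list[EnsembleMember] = []
    full_fits: list[FittedModel] = []
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(len(folds) * len(algorithms)))
    for fold_i, (tr, te) in enumerate(folds, start=1):
        for alg in algorithms:
            s = int(next(seeds)) % (2**31)
            model = fit_model(alg, X.iloc[tr], y[tr], seed=s)
            if te.size == 0:
                full_fits.append(model)
                continue
            scores = model.predict(X.iloc[te])
            thr, tss = optimize_threshold(scores, y[te])
            auc = roc_auc(scores, y[te])
            members.append(EnsembleMember(
                model=model,
                record=EvaluationRecord(alg, pa_rep, fold_i, tss, auc, thr),
            ))
    return members, full_fits


def build_ensemble(
    members: list[EnsembleMember],
    eval_scores: pd.DataFrame,
    tss_min: float = 0.75,
) -> EnsembleModel:
    """Gate members at TSS > tss_min and weight the survivors by TSS.

    ``eval_scores`` holds the pooled held-out rows (columns: the model
    variables plus ``label``); the ensemble's binarization threshold is
    TSS-optimized on its weighted-average scores over those rows.
    """
    passing = [m for m in members if m.record.tss > tss_min]
    if not passing:
        report = [(m.record.algorithm_id, m.record.pa_rep, m.record.fold,
                   m.record.tss) for m in members]
        raise EnsembleEmptyError(
            f"no member exceeded TSS {tss_min}; best = "
            f"{max((m.record.tss for m in members), default=float('nan')):.3f}",
            tss_report=report,
        )
    tss = np.array([m.record.tss for m in passing])
    weights = tss / tss.sum()
    variables = passing[0].model.variables
    ens = EnsembleModel(members=passing, weights=weights, tss_min=tss_min,
                        threshold=0.5, variables=variables)
    scores = ens.predict(eval_scores[variables])
    thr, _ = optimize_threshold(scores, eval_scores["label"].to_numpy())
    ens.threshold = thr
    return ens


def predict_map(model_or_ensemble, stack: EnvStack,
                variables: list[str] | None = None) -> RasterLayer:
    """Project a fitted model or ensemble onto a stack, cell by cell.

    Nodata cells propagate to the output.
    """
    if variables is None:
        variables = getattr(model_or_ensemble, "variables")
    missing = [v for v in variables if v not in stack]
    if missing:
        raise ConfigurationError(f"stack lacks variables {missing}")
    mask = stack.combined_mask(variables)
    rows, cols = np.nonzero(~mask)
    X = stack.table(rows, cols, variables)
    vals = np.full(stack.spec.shape, np.nan)
    vals[rows, cols] = model_or_ensemble.predict(X)
    return RasterLayer(stack.spec, vals, mask,
                       name=f"suitability_{stack.scenario_tag}")


def binarize(layer: RasterLayer, threshold: float) -> RasterLayer:
    """Threshold a suitability map into a binary presence map (≥ rule)."""
    if not (0.0 < threshold < 1.0):
        raise ConfigurationError(f"threshold must lie in (0, 1), got {threshold}")
    vals = np.where(layer.mask, np.nan, (layer.values >= threshold).astype(float))
    return RasterLayer(layer.spec, vals, layer.mask.copy(),
                       name=f"{layer.name}_bin")
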