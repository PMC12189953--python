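"""Environmental variable selection.

Candidate predictors are screened with model-based permutation importance and
then admitted greedily, highest mean importance first, subject to a pairwise
correlation cap |r| < r_max against every already-admitted variable, stopping
at k variables (defaults: r_max = 0.70, k = 6).  The correlation sample is
the modeling domain itself — presence plus pseudoabsence cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SelectionFailedError
from .grid import EnvStack
from .models import ALGORITHMS, FittedModel, fit_model


def pearson_matrix(stack: EnvStack, rows: np.ndarray, cols: np.ndarray,
                   names: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson r between layers sampled at the given cells.

    A layer constant over the sample has undefined correlations; they are set
    to 0 with a warning.  The diagonal is always 1.
    """
    names = names if names is not None else stack.names
    if len(rows) < 3:
        raise ConfigurationError("need at least 3 sample points for correlations")
    table = stack.table(np.asarray(rows), np.asarray(cols), names)
    arr = table.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant layers over correlation sample: {list(table.columns[constant])}; "
            "their correlations set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=names, columns=names)


def permutation_importance(
    model: FittedModel,
    X: pd.DataFrame,
    variable: str,
    n_shuffles: int = 3,
    seed: int = 0,
) -> float:
    """Importance of one variable to a fitted model.

    1 − mean Pearson r between predictions on the original table and on the
    table with that variable's column shuffled, clipped to [0, 1].  A variable
    the model ignores leaves predictions unchanged (r = 1, importance 0).
    """
    if variable not in model.variables:
        raise ConfigurationError(f"variable {variable!r} not among model inputs")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = model.predict(X)
    rs = []
    for _ in range(n_shuffles):
        Xs = X.copy()
        Xs[variable] = rng.permutation(Xs[variable].to_numpy())
        pred = model.predict(Xs)
        if np.allclose(pred, base):
            rs.append(1.0)
        elif np.std(pred) == 0 or np.std(base) == 0:
            rs.append(0.0)  # undefined r: no linear association
        else:
            rs.append(float(np.corrcoef(base, pred)[0, 1]))
    return float(np.clip(1.0 - np.mean(rs), 0.0, 1.0))


def screen_importances(
    X: pd.DataFrame,
    y: np.ndarray,
    algorithms: tuple[str, ...] = ALGORITHMS,
    n_shuffles: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance of every candidate variable under each learner.

    Returns a long table (variable, algorithm, importance); aggregate with
    :func:`mean_importance`.
    """
    ss = np.random.SeedSequence(seed)
    fit_seeds = ss.spawn(len(algorithms))
    rows = []
    for alg, alg_ss in zip(algorithms, fit_seeds):
        states = alg_ss.generate_state(2)
        model = fit_model(alg, X, y, seed=int(states[0]) % (2**31))
        for i, var in enumerate(X.columns):
            imp = permutation_importance(
                model, X, var, n_shuffles=n_shuffles,
                seed=int(states[1] + i) % (2**31),
            )
            rows.append({"variable": var, "algorithm": alg, "importance": imp})
    return pd.DataFrame(rows)


def mean_importance(table: pd.DataFrame) -> pd.Series:
    """Mean importance per variable across learners (descending)."""
    return table.groupby("variable")["importance"].mean().sort_values(ascending=False)


def select_variables(
    importance: pd.Series,
    correlation: pd.DataFrame,
    r_max: float = 0.70,
    k: int = 6,
) -> list[str]:
    """Greedy top-k selection under the pairwise correlation cap.

    Variables are visited in descending mean importance; one is admitted only
    if |r| < r_max against every already-admitted variable.  Stops at k or
    when candidates are exhausted; raises if fewer than two variables are
    admissible.
    """
    order = importance.sort_values(ascending=False).index
    missing = [v for v in order if v not in correlation.index]
    if missing:
        raise ConfigurationError(f"correlation matrix lacks variables {missing}")
    selected: list[str] = []
    for var in order:
        if len(selected) >= k:
            break
        if all(abs(float(correlation.loc[var, s])) < r_max for s in selected):
            selected.append(var)
    if len(selected) < 2:
        raise SelectionFailedError(
            f"only {len(selected)} variable(s) admissible under |r| < {r_max}"
        )
    return selected
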