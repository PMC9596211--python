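"""Definition, loading, evaluation and training of the small-CpG epigenetic clocks.

Four clock forms are shipped: two multiple quadratic regressions (Bekaert on
four genes, Garali MQR on ELOVL2 only), one multiple linear regression (Thong,
three genes) and one gradient-boosting regressor (Garali GBR, ELOVL2 only).
For the regression clocks a prediction is

    dnam_age = intercept + sum_k coefficient_k * methylation_k ** exponent_k

with methylation expressed as pyrosequencing percentages (0-100), never as
beta values; clock-definition files must declare ``"unit": "percent"`` and the
loader rejects anything else.

The packaged default coefficients are SYNTHETIC stand-ins: the original
published equations are not redistributable here, so the built-ins are fitted
against canonical linear methylation-vs-age trajectories (stored alongside
them in ``data/builtin_clocks_synthetic.json``) such that each clock has the
published functional form and marker set and inverts age essentially exactly
on those trajectories.  The GBR clock likewise ships as a deterministic
training recipe (seed, sample size, hyperparameters) rather than fitted
weights, and is trained on first use.

Predicted ages are never clamped: applying the clocks far beyond their 0-91 y
training range is precisely the use case of interest for centenarians, so an
out-of-range prediction is returned as-is with ``extrapolated=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .markers import MARKER_REGISTRY

__all__ = [
    "ClockTerm",
    "GBRState",
    "ClockModel",
    "AgePrediction",
    "ClockError",
    "ClockDefinitionError",
    "MissingMarkerError",
    "MethylationRangeError",
    "GBRTrainingError",
    "TRAINING_AGE_RANGE",
    "load_clock_definitions",
    "save_clock_definitions",
    "builtin_clocks",
    "builtin_regression_clocks",
    "canonical_trajectories",
    "predict_age",
    "predict_table",
    "train_gbr_clock",
]

#: Chronological age range (years) the published clocks were trained on;
#: predictions outside it are flagged as extrapolation.
TRAINING_AGE_RANGE = (0.0, 91.0)

_BUILTIN_RESOURCE = "builtin_clocks_synthetic.json"

DEFAULT_GBR_HYPERPARAMS = {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1}


class ClockError(ValueError):
    """Base class for clock definition/evaluation errors."""


class ClockDefinitionError(ClockError):
    """A clock definition is malformed or references unknown markers."""


class MissingMarkerError(ClockError):
    """A required marker is absent from the input row."""


class MethylationRangeError(ClockError):
    """A methylation value lies outside [0, 100] percent."""


class GBRTrainingError(ClockError):
    """GBR training preconditions violated."""


@dataclass(frozen=True)
class ClockTerm:
    """One polynomial term of a regression clock (years per percent**exponent)."""

    marker_id: str
    exponent: int
    coefficient: float

    def __post_init__(self) -> None:
        if self.exponent < 1 or int(self.exponent) != self.exponent:
            raise ClockDefinitionError(f"term exponent must be a positive integer, got {self.exponent}")


@dataclass
class GBRState:
    """Trained gradient-boosting ensemble plus its training metadata."""

    model: GradientBoostingRegressor
    n_training: int
    hyperparams: dict[str, Any]
    seed: int


@dataclass
class ClockModel:
    """A single epigenetic clock: functional form, markers and parameters."""

    name: str
    form: str  # "MLR" | "MQR" | "GBR"
    intercept: float | None = None
    terms: tuple[ClockTerm, ...] = ()
    required_markers: tuple[str, ...] = ()
    gbr_state: GBRState | None = None
    unit: str = "percent"

    def __post_init__(self) -> None:
        if self.form not in ("MLR", "MQR", "GBR"):
            raise ClockDefinitionError(f"clock {self.name!r}: unknown form {self.form!r}")
        if self.unit != "percent":
            raise ClockDefinitionError(
                f"clock {self.name!r}: unit must be 'percent' (0-100 pyrosequencing scale), got {self.unit!r}"
            )
        for t in self.terms:
            if t.marker_id not in MARKER_REGISTRY:
                raise ClockDefinitionError(
                    f"clock {self.name!r} references unknown marker {t.marker_id!r}"
                )
        if self.form == "GBR":
            if self.terms:
                raise ClockDefinitionError(f"GBR clock {self.name!r} must not carry regression terms")
        else:
            if self.gbr_state is not None:
                raise ClockDefinitionError(f"{self.form} clock {self.name!r} must not carry gbr_state")
            if self.intercept is None:
                raise ClockDefinitionError(f"{self.form} clock {self.name!r} requires an intercept")
            if self.form == "MLR" and any(t.exponent != 1 for t in self.terms):
                raise ClockDefinitionError(f"MLR clock {self.name!r} must use exponent 1 only")
        if not self.required_markers:
            self.required_markers = tuple(dict.fromkeys(t.marker_id for t in self.terms))
        for m in self.required_markers:
            if m not in MARKER_REGISTRY:
                raise ClockDefinitionError(f"clock {self.name!r} requires unknown marker {m!r}")


@dataclass(frozen=True)
class AgePrediction:
    """DNAm-age estimate for one sample under one clock."""

    sample_id: str
    clock_name: str
    dnam_age: float
    inputs_used: dict[str, float]
    extrapolated: bool = False


def _validate_row(clock: ClockModel, row: Mapping[str, float]) -> dict[str, float]:
    missing = [m for m in clock.required_markers if m not in row or pd.isna(row[m])]
    if missing:
        raise MissingMarkerError(
            f"clock {clock.name!r}: missing methylation for marker(s) {', '.join(missing)}"
        )
    used = {}
    for m in clock.required_markers:
        v = float(row[m])
        if not (0.0 <= v <= 100.0):
            raise MethylationRangeError(
                f"clock {clock.name!r}: marker {m} value {v} outside [0, 100] percent"
            )
        used[m] = v
    return used


def predict_age(clock: ClockModel, row: Mapping[str, float], sample_id: str = "") -> AgePrediction:
    """Evaluate one clock on one sample's marker->percent mapping.

    Raises :class:`MissingMarkerError` / :class:`MethylationRangeError` on bad
    input. The returned age is not clamped; ``extrapolated`` is set when it
    falls outside the clocks' published training range.
    """
    used = _validate_row(clock, row)
    if clock.form == "GBR":
        if clock.gbr_state is None:
            raise ClockDefinitionError(f"GBR clock {clock.name!r} has not been trained")
        x = np.array([[used[m] for m in clock.required_markers]])
        age = float(clock.gbr_state.model.predict(x)[0])
    else:
        age = float(clock.intercept)
        for t in clock.terms:
            age += t.coefficient * used[t.marker_id] ** t.exponent
    lo, hi = TRAINING_AGE_RANGE
    return AgePrediction(
        sample_id=sample_id,
        clock_name=clock.name,
        dnam_age=age,
        inputs_used=used,
        extrapolated=not (lo <= age <= hi),
    )


def predict_table(clock: ClockModel, table: pd.DataFrame) -> pd.Series:
    """Vectorized prediction over a DataFrame with marker columns.

    Rows with any required marker missing yield NaN (the caller decides how to
    report skipped samples); out-of-range methylation raises.
    """
    sub = table[list(clock.required_markers)].astype(float)
    bad = (sub < 0) | (sub > 100)
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MethylationRangeError(
            f"clock {clock.name!r}: methylation outside [0, 100] at row {table.index[r]}, "
            f"column {sub.columns[c]}"
        )
    complete = sub.notna().all(axis=1)
    out = pd.Series(np.nan, index=table.index, name=clock.name, dtype=float)
    if not complete.any():
        return out
    x = sub.loc[complete]
    if clock.form == "GBR":
        if clock.gbr_state is None:
            raise ClockDefinitionError(f"GBR clock {clock.name!r} has not been trained")
        out.loc[complete] = clock.gbr_state.model.predict(x.to_numpy())
    else:
        acc = np.full(len(x), float(clock.intercept))
        for t in clock.terms:
            acc = acc + t.coefficient * x[t.marker_id].to_numpy() ** t.exponent
        out.loc[complete] = acc
    return out


def train_gbr_clock(
    training: pd.DataFrame,
    markers: Sequence[str] = ("ELOVL2_CpG4", "ELOVL2_CpG5", "ELOVL2_CpG6"),
    hyperparams: Mapping[str, Any] | None = None,
    seed: int = 0,
    name: str = "Garali_GBR",
    age_column: str = "age_at_collection",
) -> ClockModel:
    """Fit a gradient-boosting age regressor on a cohort table.

    The fit is bit-reproducible for fixed (data, hyperparams, seed). Requires
    n >= 20 rows with complete markers and a non-constant age column.
    """
    hp = dict(DEFAULT_GBR_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    markers = tuple(markers)
    for m in markers:
        if m not in MARKER_REGISTRY:
            raise ClockDefinitionError(f"GBR training references unknown marker {m!r}")
        if m not in training.columns:
            raise GBRTrainingError(f"training table lacks marker column {m!r}")
    if age_column not in training.columns:
        raise GBRTrainingError(f"training table lacks age column {age_column!r}")
    data = training[[age_column, *markers]].dropna()
    if len(data) < 20:
        raise GBRTrainingError(f"GBR training needs n >= 20 complete rows, got {len(data)}")
    y = data[age_column].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise GBRTrainingError("age column is constant; GBR target is degenerate")
    model = GradientBoostingRegressor(random_state=int(seed), **hp)
    model.fit(data[list(markers)].to_numpy(dtype=float), y)
    return ClockModel(
        name=name,
        form="GBR",
        required_markers=markers,
        gbr_state=GBRState(model=model, n_training=len(data), hyperparams=hp, seed=int(seed)),
    )


# ---------------------------------------------------------------------------
# serialization


def _clock_to_dict(clock: ClockModel) -> dict[str, Any]:
    if clock.form == "GBR":
        st = clock.gbr_state
        d: dict[str, Any] = {
            "name": clock.name,
            "form": "GBR",
            "training": {
                "seed": st.seed if st else None,
                "n": st.n_training if st else None,
                "markers": list(clock.required_markers),
                "hyperparams": st.hyperparams if st else None,
            },
        }
        return d
    return {
        "name": clock.name,
        "form": clock.form,
        "intercept": clock.intercept,
        "terms": [
            {"marker": t.marker_id, "exponent": t.exponent, "coefficient": t.coefficient}
            for t in clock.terms
        ],
    }


def save_clock_definitions(clocks: Sequence[ClockModel], path) -> None:
    """Write a clock-definition JSON file (GBR clocks saved as training recipes)."""
    payload = {"unit": "percent", "clocks": [_clock_to_dict(c) for c in clocks]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def _parse_definitions(payload: Mapping[str, Any], source: str) -> list[ClockModel]:
    unit = payload.get("unit")
    if unit != "percent":
        raise ClockDefinitionError(
            f"{source}: clock files must declare unit='percent' (0-100 scale), got {unit!r}"
        )
    trajectories = payload.get("calibration_trajectories")
    clocks: list[ClockModel] = []
    for entry in payload["clocks"]:
        name = entry.get("name", "<unnamed>")
        form = entry.get("form")
        if form == "GBR":
            training = entry.get("training")
            if not training:
                raise ClockDefinitionError(
                    f"{source}: GBR clock {name!r} lacks a 'training' recipe (seed, n, hyperparams)"
                )
            clocks.append(_train_gbr_from_recipe(name, training, trajectories))
            continue
        terms = tuple(
            ClockTerm(t["marker"], int(t["exponent"]), float(t["coefficient"]))
            for t in entry.get("terms", ())
        )
        clocks.append(
            ClockModel(name=name, form=form, intercept=float(entry["intercept"]), terms=terms)
        )
    return clocks


def _train_gbr_from_recipe(
    name: str,
    training: Mapping[str, Any],
    trajectories: Mapping[str, Mapping[str, float]] | None,
) -> ClockModel:
    """Train a GBR clock from its deterministic recipe.

    Training data are noise-free samples of the canonical trajectories over
    the recipe's age range — a synthetic stand-in for the original (not
    redistributable) training cohort.
    """
    if trajectories is None:
        trajectories = canonical_trajectories()
    seed = int(training["seed"])
    n = int(training["n"])
    lo, hi = training.get("age_range", [5.0, 91.0])
    markers = list(training["markers"])
    ages = np.linspace(float(lo), float(hi), n)
    df = pd.DataFrame({"age_at_collection": ages})
    for m in markers:
        tr = trajectories[m]
        df[m] = float(tr["alpha"]) + float(tr["beta"]) * ages
    return train_gbr_clock(
        df, markers=markers, hyperparams=training.get("hyperparams"), seed=seed, name=name
    )


def load_clock_definitions(path) -> list[ClockModel]:
    """Load and validate clocks from a JSON definition file.

    GBR entries must carry a ``training`` recipe; they are trained
    deterministically at load time.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return _parse_definitions(payload, source=str(path))


def _builtin_payload() -> dict[str, Any]:
    text = resources.files("cpgclock.data").joinpath(_BUILTIN_RESOURCE).read_text("utf-8")
    return json.loads(text)


def canonical_trajectories() -> dict[str, dict[str, float]]:
    """Per-marker (alpha, beta) of the canonical linear methylation trajectories
    the synthetic built-in clocks were fitted against."""
    return _builtin_payload()["calibration_trajectories"]


_BUILTIN_CACHE: list[ClockModel] | None = None


def builtin_clocks() -> list[ClockModel]:
    """The four built-in clocks (synthetic stand-in coefficients; GBR trained
    from its packaged recipe on first call, then cached)."""
    global _BUILTIN_CACHE
    if _BUILTIN_CACHE is None:
        _BUILTIN_CACHE = _parse_definitions(_builtin_payload(), source="builtin registry")
    return list(_BUILTIN_CACHE)


def builtin_regression_clocks() -> list[ClockModel]:
    """Only the MLR/MQR built-ins (those with closed-form equations)."""
    return [c for c in builtin_clocks() if c.form != "GBR"]
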