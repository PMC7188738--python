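"""Linear diagnostic scoring models.

Two models are shipped as JSON fixtures with their published coefficients:

* ``rad_score`` — a radiomics signature: an intercept plus 20 weighted
  texture/shape terms computed from standardized features of the three
  co-registered modalities (FDG-PET, MET-PET, contrast MR).
* ``int_score`` — an integrated diagnostic score combining patient age
  (in raw years), the mean tumor-to-background ratio of FDG-PET, the
  maximum tumor-to-background ratio of MET-PET, and 12 standardized
  texture terms.

Both are plain linear predictors on the logit scale; ``score_to_probability``
maps them to a recurrence probability.  The published equations carry no
modality prefix on the texture-feature names, and one rad-score term name
appears twice with different weights, so every term occupies a named *slot*:
evaluation is keyed by slot, and binding slots to extracted feature columns
(which do carry a modality prefix) is an explicit user-supplied mapping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.special import expit

SCHEMA_VERSION = 1


class ModelSchemaError(ValueError):
    """Raised when a serialized model file has an unexpected layout."""


class MissingTermError(KeyError):
    """Raised when an input vector does not cover every model term."""


class AmbiguousTermError(ValueError):
    """Raised when duplicate term names cannot be resolved to slots."""


@dataclass(frozen=True)
class Term:
    """One weighted predictor of a scoring model.

    ``slot`` is the unique key used at evaluation time; ``feature`` is the
    (possibly duplicated) published feature name.  ``standardize`` is False
    for predictors entering on their raw scale (age in years).
    """

    slot: str
    feature: str
    coefficient: float
    standardize: bool = True


@dataclass
class ScoringModel:
    """Intercept plus named linear terms, with standardization provenance."""

    name: str
    intercept: float
    terms: list[Term]
    #: per-feature (mean, sd) used to standardize inputs, or None when the
    #: caller acknowledges inputs are already standardized
    standardization: dict[str, tuple[float, float]] | None = None
    link: str = "linear"

    def __post_init__(self) -> None:
        slots = [t.slot for t in self.terms]
        if len(set(slots)) != len(slots):
            raise ModelSchemaError(f"duplicate slot ids in model '{self.name}'")

    # -- introspection ----------------------------------------------------
    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def slots(self) -> list[str]:
        return [t.slot for t in self.terms]

    def zero_input(self) -> dict[str, float]:
        """An input vector with every slot set to 0 (the model's baseline)."""
        return {t.slot: 0.0 for t in self.terms}

    def _duplicated_features(self) -> set[str]:
        names = [t.feature for t in self.terms]
        return {n for n in names if names.count(n) > 1}

    # -- evaluation -------------------------------------------------------
    def evaluate(
        self,
        values: Mapping[str, float],
        mapping: Mapping[str, str] | None = None,
    ) -> float:
        """Linear predictor ``intercept + sum(coef * value)``.

        ``values`` is keyed by slot id (or by feature name where unambiguous).
        ``mapping`` optionally binds slot ids to keys of ``values`` — the
        mechanism by which published term names, which carry no modality
        prefix, are tied to extracted feature columns.
        """
        duplicated = self._duplicated_features()
        score = self.intercept
        missing: list[str] = []
        for term in self.terms:
            key = term.slot
            if mapping is not None and term.slot in mapping:
                key = mapping[term.slot]
            if key not in values:
                if term.feature in values:
                    if term.feature in duplicated:
                        raise AmbiguousTermError(
                            f"term '{term.feature}' appears more than once in "
                            f"model '{self.name}'; key inputs by slot id "
                            f"({[t.slot for t in self.terms if t.feature == term.feature]}) "
                            "or supply a slot mapping"
                        )
                    key = term.feature
                else:
                    missing.append(term.slot)
                    continue
            v = float(values[key])
            if not math.isfinite(v):
                raise ValueError(f"non-finite input for term '{term.slot}': {v}")
            if term.standardize and self.standardization is not None:
                mean, sd = self.standardization[term.feature]
                v = (v - mean) / sd
            score += term.coefficient * v
        if missing:
            raise MissingTermError(
                f"model '{self.name}' is missing input(s): {missing}"
            )
        return score

    def evaluate_table(self, table, mapping: Mapping[str, str] | None = None):
        """Evaluate the model on each row of a DataFrame; returns a Series."""
        import pandas as pd

        scores = [
            self.evaluate(row.to_dict(), mapping=mapping)
            for _, row in table.iterrows()
        ]
        return pd.Series(scores, index=table.index, name=self.name)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "intercept": self.intercept,
            "link": self.link,
            "terms": [
                {
                    "slot": t.slot,
                    "feature": t.feature,
                    "coefficient": t.coefficient,
                    "standardize": t.standardize,
                }
                for t in self.terms
            ],
        }
        if self.standardization is None:
            d["standardization"] = None
        else:
            d["standardization"] = {
                k: {"mean": m, "sd": s} for k, (m, s) in self.standardization.items()
            }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringModel":
        if not isinstance(d, dict) or "schema_version" not in d:
            raise ModelSchemaError("missing 'schema_version'")
        if d["schema_version"] != SCHEMA_VERSION:
            raise ModelSchemaError(
                f"unknown schema_version {d['schema_version']!r}"
            )
        for key in ("intercept", "terms", "name"):
            if key not in d:
                raise ModelSchemaError(f"missing required field '{key}'")
        std = d.get("standardization")
        if std is not None:
            std = {k: (v["mean"], v["sd"]) for k, v in std.items()}
        terms = [
            Term(
                slot=t["slot"],
                feature=t.get("feature", t["slot"]),
                coefficient=float(t["coefficient"]),
                standardize=bool(t.get("standardize", True)),
            )
            for t in d["terms"]
        ]
        return cls(
            name=d["name"],
            intercept=float(d["intercept"]),
            terms=terms,
            standardization=std,
            link=d.get("link", "linear"),
        )

    @classmethod
    def from_json(cls, text: str) -> "ScoringModel":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ModelSchemaError(f"not valid JSON: {exc}") from exc
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# packaged published models
# ---------------------------------------------------------------------------

def _load_packaged(basename: str) -> ScoringModel:
    text = (
        resources.files("gliorad").joinpath("models", basename).read_text("utf-8")
    )
    return ScoringModel.from_json(text)


_CACHE: dict[str, ScoringModel] = {}


def load_rad_score_model() -> ScoringModel:
    """The published 20-term radiomics-signature model (rad-score)."""
    if "rad" not in _CACHE:
        _CACHE["rad"] = _load_packaged("rad_score_paper.json")
    return _CACHE["rad"]


def load_int_score_model() -> ScoringModel:
    """The published 15-predictor integrated model (int-score)."""
    if "int" not in _CACHE:
        _CACHE["int"] = _load_packaged("int_score_paper.json")
    return _CACHE["int"]


def rad_score(
    features: Mapping[str, float], mapping: Mapping[str, str] | None = None
) -> float:
    """Evaluate the published radiomics signature on standardized features."""
    return load_rad_score_model().evaluate(features, mapping=mapping)


def int_score(
    age: float,
    tbr_mean_fdg: float,
    tbr_max_met: float,
    features: Mapping[str, float],
    mapping: Mapping[str, str] | None = None,
) -> float:
    """Evaluate the published integrated score.

    ``age`` enters in raw years; the tumor-to-background ratios and texture
    features are supplied on the scale the model was fitted on.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    values = dict(features)
    values["age"] = age
    values["TBRmean"] = tbr_mean_fdg
    values["TBRmax"] = tbr_max_met
    return load_int_score_model().evaluate(values, mapping=mapping)


def score_to_probability(score: float | np.ndarray) -> float | np.ndarray:
    """Logistic transform 1/(1+exp(-score)); strictly increasing."""
    return expit(score)


def build_model(fit, stats: dict[str, tuple[float, float]] | None, name: str = "fitted") -> ScoringModel:
    """Package a fitted sparse logistic model as a ScoringModel.

    ``fit`` must expose ``intercept`` and a name->coefficient mapping
    ``coefficients`` (zeros excluded); ``stats`` are the per-feature
    (mean, sd) used to standardize the training table, or None when the
    model is to be applied to pre-standardized inputs.
    """
    import logging

    terms = [
        Term(slot=n, feature=n, coefficient=float(b))
        for n, b in fit.coefficients.items()
        if b != 0.0
    ]
    if not terms:
        logging.getLogger(__name__).warning(
            "fit has no nonzero coefficients; building intercept-only model"
        )
    return ScoringModel(
        name=name,
        intercept=float(fit.intercept),
        terms=terms,
        standardization=stats,
    )
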