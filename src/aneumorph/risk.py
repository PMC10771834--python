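"""Threshold flags and logistic rupture-resemblance scores (RRS).

Each measured parameter is compared against a literature cutoff with a
direction (high SR, high OSI, low NWSS, ... are the rupture-associated
sides); a flag is raised on a *strict* exceedance. Three logistic models
turn parameter panels into rupture-resemblance probabilities:

    RRS_M  morphology only          (size ratio SR)
    RRS_H  hemodynamics only        (NWSS, OSI)
    RRS_C  combined                 (SR, NWSS, OSI)

with RRS = 1 / (1 + exp(-(b0 + sum_i b_i x_i))) and an optional natural-log
transform per feature (OSI and NWSS span decades, so their published models
are usually fit on the log scale). A score above the 30 % cutoff reads
"resembles the ruptured population".

The slope/intercept blocks of the originally published models are not
redistributable here; the shipped defaults in
``data/rrs_coefficients_synthetic.json`` are synthetic illustrative values
with the published sign structure (risk increases with SR and OSI, decreases
with NWSS). Supply your own coefficient JSON for a validated model, or refit
one on a labelled parameter table with :func:`fit_logistic`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .types import ConfigError, HemodynamicsResult, MorphometryResult, ValidationError

__all__ = [
    "ThresholdConfig",
    "RRSCoefficients",
    "RiskPanel",
    "classify",
    "rrs_probability",
    "decide",
    "score_panel",
    "fit_logistic",
    "load_default_thresholds",
    "load_default_coefficients",
    "load_bundled_cases",
    "RRS_CUTOFF",
]

RRS_CUTOFF = 0.30


def _data_text(name: str) -> str:
    return resources.files("aneumorph.data").joinpath(name).read_text()


@dataclass
class ThresholdConfig:
    """Per-parameter decision rules: name -> (direction, cutoff).

    ``direction`` is ``"greater"`` or ``"less"``: the side of the cutoff
    associated with rupture.
    """

    rules: dict[str, tuple[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (direction, cutoff) in self.rules.items():
            if direction not in ("greater", "less"):
                raise ConfigError(f"threshold {name!r}: direction must be greater/less")
            if not math.isfinite(cutoff):
                raise ConfigError(f"threshold {name!r}: cutoff must be finite")

    @classmethod
    def from_json(cls, source: str | Path) -> "ThresholdConfig":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        raw = json.loads(text)
        return cls({k: (v["direction"], float(v["cutoff"])) for k, v in raw.items()})

    def to_json(self) -> str:
        return json.dumps(
            {k: {"direction": d, "cutoff": c} for k, (d, c) in self.rules.items()}, indent=1
        )


def load_default_thresholds() -> ThresholdConfig:
    """The bundled literature cutoffs (thetaF > 118.25 deg, SR > 1.75,
    NWSS < 0.39, OSI > 0.0036, RRS > 30 %, ...)."""
    raw = json.loads(_data_text("thresholds.json"))
    return ThresholdConfig({k: (v["direction"], float(v["cutoff"])) for k, v in raw.items()})


def classify(
    values: Mapping[str, Optional[float]],
    config: Optional[ThresholdConfig] = None,
    parameters: Optional[Sequence[str]] = None,
) -> dict[str, Optional[bool]]:
    """Flag parameters that strictly exceed their cutoff in the configured
    direction; None values give None flags.

    ``parameters`` restricts (and checks) which names to flag; by default
    every supplied value with a configured rule is flagged. An explicitly
    requested name without a rule raises ConfigError.
    """
    config = config or load_default_thresholds()
    if parameters is None:
        names = [n for n in values if n in config.rules]
    else:
        unknown = [n for n in parameters if n not in config.rules]
        if unknown:
            raise ConfigError(f"no threshold configured for: {', '.join(unknown)}")
        names = list(parameters)
    flags: dict[str, Optional[bool]] = {}
    for name in names:
        v = values.get(name)
        if v is None:
            flags[name] = None
            continue
        direction, cutoff = config.rules[name]
        flags[name] = v > cutoff if direction == "greater" else v < cutoff
    return flags


@dataclass
class RRSCoefficients:
    """One logistic model: intercept plus (feature, slope, transform) terms.

    ``transform`` is ``"identity"`` or ``"log"`` (natural log, applied to the
    feature before multiplying by the slope).
    """

    model: str
    intercept: float
    terms: list[tuple[str, float, str]]

    def __post_init__(self) -> None:
        for name, slope, transform in self.terms:
            if transform not in ("identity", "log"):
                raise ConfigError(f"model {self.model}: unknown transform {transform!r}")
            if not math.isfinite(slope):
                raise ConfigError(f"model {self.model}: non-finite slope for {name}")

    @property
    def features(self) -> list[str]:
        return [name for name, _, _ in self.terms]


def _parse_coefficients(raw: dict) -> dict[str, RRSCoefficients]:
    out = {}
    for model, block in raw.items():
        if model.startswith("_"):
            continue
        out[model] = RRSCoefficients(
            model=model,
            intercept=float(block["intercept"]),
            terms=[
                (t["feature"], float(t["slope"]), t.get("transform", "identity"))
                for t in block["terms"]
            ],
        )
    return out


def load_default_coefficients() -> dict[str, RRSCoefficients]:
    """The bundled synthetic illustrative coefficient sets for models M, H, C.

    These are placeholders with physiologically sensible sign structure, not
    a validated clinical model; see the module docstring.
    """
    return _parse_coefficients(json.loads(_data_text("rrs_coefficients_synthetic.json")))


def load_coefficients(source: str | Path) -> dict[str, RRSCoefficients]:
    """Load user-supplied coefficient sets from a JSON file or string."""
    text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
    return _parse_coefficients(json.loads(text))


def rrs_probability(features: Mapping[str, float], coeffs: RRSCoefficients) -> float:
    """Logistic probability 1/(1 + exp(-(b0 + sum slope_i * transform_i(x_i))))."""
    z = coeffs.intercept
    for name, slope, transform in coeffs.terms:
        x = features.get(name)
        if x is None:
            raise ValidationError(f"RRS_{coeffs.model}: missing feature {name!r}")
        x = float(x)
        if not math.isfinite(x):
            raise ValidationError(f"RRS_{coeffs.model}: non-finite feature {name!r}")
        if transform == "log":
            if x <= 0:
                raise ValidationError(
                    f"RRS_{coeffs.model}: log transform of non-positive {name} = {x}"
                )
            x = math.log(x)
        z += slope * x
    return 1.0 / (1.0 + math.exp(-z))


def decide(rrs: float, cutoff: float = RRS_CUTOFF) -> bool:
    """Rupture-resemblance decision: strictly above the cutoff (default 30 %)."""
    if not 0.0 <= rrs <= 1.0:
        raise ValidationError(f"RRS must be a probability, got {rrs}")
    return rrs > cutoff


@dataclass
class RiskPanel:
    """Everything the report prints: measurements, flags, scores, decisions."""

    morphometry: Optional[MorphometryResult | dict] = None
    hemodynamics: Optional[HemodynamicsResult | dict] = None
    flags: dict = field(default_factory=dict)
    rrs: dict = field(default_factory=dict)  # model -> probability
    decisions: dict = field(default_factory=dict)  # model -> bool
    thresholds: Optional[ThresholdConfig] = None


def score_panel(
    values: Mapping[str, Optional[float]],
    coefficient_sets: Optional[dict[str, RRSCoefficients]] = None,
    thresholds: Optional[ThresholdConfig] = None,
    cutoff: float = RRS_CUTOFF,
    morphometry: Optional[MorphometryResult] = None,
    hemodynamics: Optional[HemodynamicsResult] = None,
) -> RiskPanel:
    """Score a parameter panel: threshold flags plus RRS for each model whose
    features are all present.

    ``values`` maps parameter names (SR, OSI, NWSS, UI, ...) to numbers or
    None. Models with missing features yield no score rather than an error,
    matching panels measured without hemodynamics.
    """
    thresholds = thresholds or load_default_thresholds()
    coefficient_sets = coefficient_sets or load_default_coefficients()
    flags = classify(values, thresholds)
    rrs: dict[str, float] = {}
    decisions: dict[str, bool] = {}
    for model, coeffs in coefficient_sets.items():
        if any(values.get(f) is None for f in coeffs.features):
            continue
        try:
            p = rrs_probability(values, coeffs)
        except ValidationError:
            # e.g. log transform of an exactly-zero OSI under steady flow:
            # the model is undefined there, so report no score for it
            continue
        rrs[model] = p
        decisions[model] = decide(p, cutoff)
        flag_name = f"RRS_{model}"
        if flag_name in thresholds.rules:
            flags[flag_name] = classify({flag_name: p}, thresholds)[flag_name]
    return RiskPanel(
        morphometry=morphometry if morphometry is not None else dict(values),
        hemodynamics=hemodynamics,
        flags=flags,
        rrs=rrs,
        decisions=decisions,
        thresholds=thresholds,
    )


def fit_logistic(
    table,
    features: Sequence[str],
    label: str,
    transforms: Optional[Mapping[str, str]] = None,
    model_name: str = "custom",
) -> RRSCoefficients:
    """Refit an RRS-style model by maximum-likelihood logistic regression on
    a labelled parameter table (secondary plumbing for when no published
    coefficient block is available).

    ``table`` is a pandas DataFrame with one row per aneurysm, the listed
    feature columns, and a binary ``label`` column (1 = ruptured).
    """
    import statsmodels.api as sm

    transforms = dict(transforms or {})
    X = []
    for f in features:
        col = np.asarray(table[f], dtype=float)
        if transforms.get(f, "identity") == "log":
            if np.any(col <= 0):
                raise ValidationError(f"log transform of non-positive column {f!r}")
            col = np.log(col)
        X.append(col)
    X = sm.add_constant(np.column_stack(X))
    y = np.asarray(table[label], dtype=float)
    fit = sm.Logit(y, X).fit(disp=False)
    params = np.asarray(fit.params, dtype=float)
    return RRSCoefficients(
        model=model_name,
        intercept=float(params[0]),
        terms=[
            (f, float(params[i + 1]), transforms.get(f, "identity"))
            for i, f in enumerate(features)
        ],
    )


def load_bundled_cases() -> dict[str, dict[str, Optional[float]]]:
    """Bundled measured parameter panels of three posterior-communicating
    artery aneurysms (two patients: a ruptured/unruptured mirror pair, and
    one aneurysm imaged two years apart), used by the worked example and the
    regression tests. RRS entries are probabilities in [0, 1]."""
    return json.loads(_data_text("printed_cases.json"))
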