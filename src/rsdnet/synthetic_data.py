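"""Heart-disease-like synthetic tabular data.

The generator emulates the schema of the classic 13-attribute clinical heart
dataset (age, sex, chest-pain type, resting blood pressure, cholesterol,
blood sugar, resting ECG, maximum heart rate, exercise-induced angina, ST
depression, ST slope, number of major vessels, thallium result) with a binary
"disease absent/present" label at the study's 150:120 class balance.

Continuous features are drawn from truncated normals inside their declared
supports; categoricals from fixed category probabilities.  Labels follow a
logistic model on the [0, 1]-scaled features,

    y ~ Bernoulli( sigmoid( effect . x_scaled + intercept + N(0, noise) ) ),

with the intercept solved numerically on the drawn sample so the expected
share of label 0 equals ``class_balance``.  Only the schema supports and the
class balance imitate the real data; marginal shapes, feature correlations
and effect magnitudes are the generator's own choices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .preprocess import FeatureTable, write_table

KINDS = ("continuous", "binary", "ordinal")


@dataclass(frozen=True)
class FeatureSpec:
    """One column: a truncated normal on [low, high] (continuous) or a
    categorical over ``categories`` with probabilities ``probs``."""

    name: str
    kind: str
    low: float = 0.0
    high: float = 1.0
    mean: float = 0.0
    sd: float = 1.0
    categories: tuple = ()
    probs: tuple = ()

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "continuous":
            if not self.low < self.high:
                raise ValueError(f"{self.name}: low must be < high")
            if self.sd <= 0:
                raise ValueError(f"{self.name}: sd must be positive")
        else:
            if len(self.categories) < 2:
                raise ValueError(f"{self.name}: need >= 2 categories")
            if len(self.probs) != len(self.categories):
                raise ValueError(f"{self.name}: probs/categories length mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-9 or min(self.probs) < 0:
                raise ValueError(f"{self.name}: probs must be a distribution")

    @property
    def support(self) -> tuple:
        if self.kind == "continuous":
            return (self.low, self.high)
        return (min(self.categories), max(self.categories))


@dataclass(frozen=True)
class SchemaSpec:
    """Feature descriptors plus the label model.

    ``class_balance`` is the target proportion of label 0 (disease absent),
    default 150/270.  ``effect_vector`` holds logistic coefficients on the
    [0, 1]-scaled features; ``noise_scale`` is the sd of Gaussian noise added
    to the logit.
    """

    features: tuple
    class_balance: float = 150.0 / 270.0
    noise_scale: float = 0.0
    effect_vector: tuple = ()

    def __post_init__(self):
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if len(self.effect_vector) not in (0, len(self.features)):
            raise ValueError("effect_vector length must match feature count")

    @property
    def names(self) -> list:
        return [f.name for f in self.features]


#: moderate logistic effects on scaled features; weight is carried by age,
#: maximum heart rate and ST depression plus smaller clinical contributions
_MODERATE_EFFECTS = {
    "age": 2.5,
    "chest_pain": 1.5,
    "max_hr": -2.5,
    "st_depression": 2.5,
    "angina": 1.0,
    "vessels": 1.5,
    "thal": 1.0,
}


def heart_schema(class_balance: float = 150.0 / 270.0, noise_scale: float = 0.0,
                 effect_scale: float = 1.0) -> SchemaSpec:
    """The default 13-attribute heart schema.

    ``effect_scale`` multiplies the moderate effect vector; ``effect_scale=8``
    is the documented "strong signal" preset (Monte-Carlo Bayes accuracy of
    the label model ~0.95) used for recovery checks.
    """
    feats = (
        FeatureSpec("age", "continuous", low=25, high=80, mean=54, sd=9),
        FeatureSpec("sex", "binary", categories=(0, 1), probs=(0.32, 0.68)),
        FeatureSpec("chest_pain", "ordinal", categories=(1, 2, 3, 4),
                    probs=(0.17, 0.16, 0.29, 0.38)),
        FeatureSpec("rest_bp", "continuous", low=94, high=200, mean=131, sd=17),
        FeatureSpec("chol", "continuous", low=126, high=564, mean=246, sd=50),
        FeatureSpec("blood_sugar", "continuous", low=120, high=400, mean=160, sd=45),
        FeatureSpec("ecg", "ordinal", categories=(0, 1, 2), probs=(0.49, 0.02, 0.49)),
        FeatureSpec("max_hr", "continuous", low=71, high=202, mean=150, sd=23),
        FeatureSpec("angina", "binary", categories=(0, 1), probs=(0.67, 0.33)),
        FeatureSpec("st_depression", "continuous", low=0, high=6.2, mean=1.05, sd=1.1),
        FeatureSpec("st_slope", "ordinal", categories=(1, 2, 3),
                    probs=(0.48, 0.46, 0.06)),
        FeatureSpec("vessels", "ordinal", categories=(0, 1, 2, 3),
                    probs=(0.55, 0.22, 0.13, 0.10)),
        FeatureSpec("thal", "ordinal", categories=(3, 6, 7),
                    probs=(0.55, 0.07, 0.38)),
    )
    effects = tuple(
        effect_scale * _MODERATE_EFFECTS.get(f.name, 0.0) for f in feats
    )
    return SchemaSpec(features=feats, class_balance=class_balance,
                      noise_scale=noise_scale, effect_vector=effects)


def strong_heart_schema(noise_scale: float = 0.0) -> SchemaSpec:
    """Heart schema with the strong (8x moderate) effect preset."""
    return heart_schema(noise_scale=noise_scale, effect_scale=8.0)


def _draw_feature(f: FeatureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if f.kind == "continuous":
        a = (f.low - f.mean) / f.sd
        b = (f.high - f.mean) / f.sd
        return truncnorm.rvs(a, b, loc=f.mean, scale=f.sd, size=n, random_state=rng)
    return rng.choice(np.asarray(f.categories, dtype=float), size=n, p=f.probs)


def _scale_to_support(x: np.ndarray, f: FeatureSpec) -> np.ndarray:
    lo, hi = f.support
    return (x - lo) / (hi - lo)


def generate(schema: SchemaSpec, n: int, seed: int = 0) -> FeatureTable:
    """Draw n instances from the schema; reproducible by seed."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    cols = [_draw_feature(f, n, rng) for f in schema.features]
    X = np.column_stack(cols)
    scaled = np.column_stack(
        [_scale_to_support(c, f) for c, f in zip(cols, schema.features)]
    )
    eff = np.asarray(schema.effect_vector or np.zeros(len(schema.features)))
    z = scaled @ eff
    if schema.noise_scale > 0:
        z = z + rng.normal(0.0, schema.noise_scale, size=n)
    target_p1 = 1.0 - schema.class_balance  # expected share of label 1

    def share_gap(b):
        return expit(z + b).mean() - target_p1

    intercept = brentq(share_gap, -60.0, 60.0)
    labels = (rng.random(n) < expit(z + intercept)).astype(int)
    return FeatureTable(X, schema.names, labels)


def generate_separable(n: int, dim: int, margin: float, seed: int = 0,
                       scale: float = 1.0) -> FeatureTable:
    """Two Gaussian blobs (sd ``scale``) centered at +/- margin * u for a
    random unit direction u; labels identify the blob."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=dim)
    u /= np.linalg.norm(u)
    labels = np.zeros(n, dtype=int)
    labels[n // 2:] = 1
    centers = np.where(labels[:, None] == 1, margin * u, -margin * u)
    X = centers + rng.normal(0.0, scale, size=(n, dim))
    perm = rng.permutation(n)
    names = [f"x{i + 1}" for i in range(dim)]
    return FeatureTable(X[perm], names, labels[perm])


def simulate_to_csv(path, schema: SchemaSpec, n: int, seed: int = 0,
                    sidecar_path=None) -> FeatureTable:
    """Write a generated table as CSV plus a JSON sidecar recording the
    schema, seed and true effect vector."""
    table = generate(schema, n, seed)
    write_table(table, path)
    sidecar = sidecar_path or (str(path) + ".json")
    meta = {
        "n": n,
        "seed": seed,
        "class_balance": schema.class_balance,
        "noise_scale": schema.noise_scale,
        "effect_vector": dict(zip(schema.names, schema.effect_vector)),
        "features": [
            {"name": f.name, "kind": f.kind, "support": list(f.support)}
            for f in schema.features
        ],
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=2)
    return table
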