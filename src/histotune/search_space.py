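"""Normalized hyperparameter search space for transfer-learning configuration search.

Candidate solutions live on the unit hypercube ``[0, 1]^D``.  Each coordinate
is tied to one hyperparameter *span* — an ordered list of admissible values
(categorical / stepped-numeric / boolean spans) or a pair of continuous
bounds.  Decoding maps a normalized element ``v`` of a solution vector to a
concrete value:

* discrete spans: 1-based index ``clamp(ceil(v * L), 1, L)`` over the ``L``
  ordered options (so ``v = 0.75`` over a 12-option batch-size span
  ``4, 8, ..., 48`` selects index 9, i.e. batch size 36);
* continuous spans: the linear map ``lower + v * (upper - lower)``.

The default space has 7 dimensions for the core training hyperparameters,
or 15 when the data-augmentation block (on/off gate plus its 8 operator
magnitudes) is searched as well.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import yaml

from .preprocessing import AugmentationConfig

__all__ = [
    "HyperparameterSpan",
    "SearchSpace",
    "DecodedConfiguration",
    "DecodeDomainError",
    "build_default_space",
    "init_population",
    "decode_element",
    "decode_solution",
    "clip_to_bounds",
    "config_steps",
    "LOSS_OPTIONS",
    "OPTIMIZER_OPTIONS",
    "SCALING_OPTIONS",
]


class DecodeDomainError(ValueError):
    """A normalized solution element fell outside ``[0, 1]``."""


#: Ordered loss-function options (6 choices).
LOSS_OPTIONS = (
    "categorical_crossentropy",
    "categorical_hinge",
    "poisson",
    "squared_hinge",
    "kl_divergence",
    "hinge",
)

#: Ordered weight-optimizer options (11 choices).
OPTIMIZER_OPTIONS = (
    "adam",
    "nadam",
    "adagrad",
    "adadelta",
    "sgd",
    "sgd_nesterov",
    "ftrl",
    "rmsprop_centered",
    "adamax",
    "rmsprop",
    "adam_amsgrad",
)

#: Ordered per-image intensity scaling options (4 choices).
SCALING_OPTIONS = ("normalize", "standard", "minmax", "maxabs")


@dataclass(frozen=True)
class HyperparameterSpan:
    """One searchable hyperparameter dimension.

    Parameters
    ----------
    name
        Identifier of the hyperparameter.
    kind
        ``"categorical"``, ``"stepped"``, ``"continuous"`` or ``"boolean"``.
    options
        Ordered admissible values for discrete kinds; ``None`` for continuous.
    bounds
        ``(lower, upper)`` for continuous spans; ``None`` otherwise.
    step
        Numeric increment for stepped spans.
    """

    name: str
    kind: str
    options: tuple | None = None
    bounds: tuple[float, float] | None = None
    step: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "stepped", "continuous", "boolean"):
            raise ValueError(f"unknown span kind {self.kind!r}")
        if self.kind == "continuous":
            if self.bounds is None or not self.bounds[0] < self.bounds[1]:
                raise ValueError(f"span {self.name!r}: continuous bounds must satisfy lower < upper")
        else:
            if self.options is None or len(self.options) < 2:
                raise ValueError(f"span {self.name!r}: discrete spans need at least 2 options")

    @classmethod
    def categorical(cls, name: str, options: Sequence) -> "HyperparameterSpan":
        return cls(name=name, kind="categorical", options=tuple(options))

    @classmethod
    def boolean(cls, name: str) -> "HyperparameterSpan":
        # Option order [True, False]: an all-zero element decodes to "yes".
        return cls(name=name, kind="boolean", options=(True, False))

    @classmethod
    def stepped(cls, name: str, lower: float, upper: float, step: float) -> "HyperparameterSpan":
        n = int(math.floor((upper - lower) / step)) + 1
        options = tuple(
            int(lower + i * step) if float(lower + i * step).is_integer() else lower + i * step
            for i in range(n)
        )
        return cls(name=name, kind="stepped", options=options, step=step)

    @classmethod
    def continuous(cls, name: str, lower: float, upper: float) -> "HyperparameterSpan":
        return cls(name=name, kind="continuous", bounds=(float(lower), float(upper)))

    @property
    def is_discrete(self) -> bool:
        return self.kind != "continuous"

    @property
    def n_options(self) -> int:
        if not self.is_discrete:
            raise ValueError(f"span {self.name!r} is continuous")
        return len(self.options)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"name": self.name, "kind": self.kind}
        if self.is_discrete:
            d["options"] = list(self.options)
            if self.step is not None:
                d["step"] = self.step
        else:
            d["bounds"] = list(self.bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HyperparameterSpan":
        if d["kind"] == "continuous":
            return cls(name=d["name"], kind="continuous", bounds=tuple(d["bounds"]))
        return cls(
            name=d["name"],
            kind=d["kind"],
            options=tuple(d["options"]),
            step=d.get("step"),
        )


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of hyperparameter spans; dimensionality ``D = len(spans)``."""

    spans: tuple[HyperparameterSpan, ...]
    includes_augmentation: bool

    @property
    def D(self) -> int:
        return len(self.spans)

    def span(self, name: str) -> HyperparameterSpan:
        for s in self.spans:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "includes_augmentation": self.includes_augmentation,
            "spans": [s.to_dict() for s in self.spans],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SearchSpace":
        return cls(
            spans=tuple(HyperparameterSpan.from_dict(s) for s in d["spans"]),
            includes_augmentation=bool(d["includes_augmentation"]),
        )

    def save(self, path) -> None:
        """Serialize to YAML (JSON-compatible dialect)."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SearchSpace":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class DecodedConfiguration:
    """Concrete hyperparameters obtained by decoding one solution vector."""

    loss_function: str
    batch_size: int
    dropout: float
    tl_learn_ratio: int
    parameter_optimizer: str
    scaling_technique: str
    apply_augmentation: bool
    augmentation: AugmentationConfig | None = None

    def __post_init__(self) -> None:
        if self.apply_augmentation != (self.augmentation is not None):
            raise ValueError("augmentation settings must be present iff apply_augmentation is true")

    def to_dict(self) -> dict:
        d = {
            "loss_function": self.loss_function,
            "batch_size": self.batch_size,
            "dropout": self.dropout,
            "tl_learn_ratio": self.tl_learn_ratio,
            "parameter_optimizer": self.parameter_optimizer,
            "scaling_technique": self.scaling_technique,
            "apply_augmentation": self.apply_augmentation,
        }
        if self.augmentation is not None:
            d["augmentation"] = self.augmentation.to_dict()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


_CORE_SPANS = (
    lambda: HyperparameterSpan.categorical("loss_function", LOSS_OPTIONS),
    lambda: HyperparameterSpan.stepped("batch_size", 4, 48, 4),
    lambda: HyperparameterSpan.continuous("dropout", 0.0, 0.6),
    lambda: HyperparameterSpan.stepped("tl_learn_ratio", 1, 100, 1),
    lambda: HyperparameterSpan.categorical("parameter_optimizer", OPTIMIZER_OPTIONS),
    lambda: HyperparameterSpan.categorical("scaling_technique", SCALING_OPTIONS),
    lambda: HyperparameterSpan.boolean("apply_augmentation"),
)

_AUGMENTATION_SPANS = (
    lambda: HyperparameterSpan.stepped("rotation", 0, 45, 1),
    lambda: HyperparameterSpan.continuous("width_shift", 0.0, 0.25),
    lambda: HyperparameterSpan.continuous("height_shift", 0.0, 0.25),
    lambda: HyperparameterSpan.continuous("shear", 0.0, 0.25),
    lambda: HyperparameterSpan.continuous("zoom", 0.0, 0.25),
    lambda: HyperparameterSpan.boolean("horizontal_flip"),
    lambda: HyperparameterSpan.boolean("vertical_flip"),
    lambda: HyperparameterSpan.continuous("brightness", 0.5, 2.0),
)


def build_default_space(include_augmentation: bool = True) -> SearchSpace:
    """Build the default 7- or 15-dimensional search space.

    Dimension order: loss function, batch size, dropout, TL learn ratio,
    parameter optimizer, scaling technique, augmentation on/off, then (when
    ``include_augmentation``) rotation, width shift, height shift, shear,
    zoom, horizontal flip, vertical flip, brightness.
    """
    spans = [f() for f in _CORE_SPANS]
    if include_augmentation:
        spans.extend(f() for f in _AUGMENTATION_SPANS)
    else:
        # Without a searched augmentation block, dimension 7 still gates
        # whether the fixed balancing augmentation is applied; it remains a
        # boolean span so D = 7.
        pass
    return SearchSpace(spans=tuple(spans), includes_augmentation=include_augmentation)


def init_population(n_solutions: int, space: SearchSpace, seed: int) -> np.ndarray:
    """Draw ``n_solutions`` uniform solution vectors in ``[0, 1]^D``.

    Deterministic for a fixed seed.  Raises ``ValueError`` for populations
    of fewer than two members.
    """
    if n_solutions < 2:
        raise ValueError("a population needs at least 2 solutions")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=(n_solutions, space.D))


def clip_to_bounds(vector: np.ndarray) -> np.ndarray:
    """Repair a solution vector by clamping every element to ``[0, 1]``."""
    return np.clip(np.asarray(vector, dtype=float), 0.0, 1.0)


def decode_element(value: float, span: HyperparameterSpan):
    """Map one normalized element to its concrete hyperparameter value."""
    if not 0.0 <= value <= 1.0:
        raise DecodeDomainError(f"element {value} outside [0, 1] for span {span.name!r}")
    if span.kind == "continuous":
        lo, hi = span.bounds
        return lo + value * (hi - lo)
    length = span.n_options
    index = min(max(math.ceil(value * length), 1), length)  # 1-based, clamped
    return span.options[index - 1]


def _decode_brightness_pair(value: float, span: HyperparameterSpan) -> tuple[float, float]:
    # A single element deterministically yields a (low, high) multiplier
    # pair: low moves linearly across the span and high sits `value` of the
    # way from low to the upper bound, so value 0 gives the degenerate
    # (0.5, 0.5) pair.
    lo, hi = span.bounds
    low = lo + value * (hi - lo)
    high = low + value * (hi - low)
    return (low, high)


def decode_solution(vector: np.ndarray, space: SearchSpace) -> DecodedConfiguration:
    """Decode a full solution vector into a concrete configuration.

    Elements are decoded in span order.  When the augmentation gate
    (dimension 7) decodes to "no", the augmentation dimensions are ignored
    and absent from the result.
    """
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or vector.shape[0] != space.D:
        raise ValueError(f"expected a {space.D}-dimensional vector, got shape {vector.shape}")
    values: dict[str, Any] = {}
    for v, span in zip(vector, space.spans):
        if span.name == "brightness":
            values[span.name] = _decode_brightness_pair(float(v), span)
        else:
            values[span.name] = decode_element(float(v), span)

    apply_aug = bool(values["apply_augmentation"])
    augmentation = None
    if apply_aug and space.includes_augmentation:
        augmentation = AugmentationConfig(
            rotation_deg=float(values["rotation"]),
            width_shift=values["width_shift"],
            height_shift=values["height_shift"],
            shear=values["shear"],
            zoom=values["zoom"],
            brightness=values["brightness"],
            horizontal_flip=values["horizontal_flip"],
            vertical_flip=values["vertical_flip"],
        )
    elif apply_aug:
        # 7-D space: the gate is searched but the operator magnitudes are
        # not; fall back to the fixed balancing defaults.
        augmentation = AugmentationConfig.balancing_defaults()
    return DecodedConfiguration(
        loss_function=values["loss_function"],
        batch_size=int(values["batch_size"]),
        dropout=float(values["dropout"]),
        tl_learn_ratio=int(values["tl_learn_ratio"]),
        parameter_optimizer=values["parameter_optimizer"],
        scaling_technique=values["scaling_technique"],
        apply_augmentation=apply_aug,
        augmentation=augmentation,
    )


def _element_index(value, span: HyperparameterSpan) -> int:
    return span.options.index(value)


def config_steps(a: DecodedConfiguration, b: DecodedConfiguration, space: SearchSpace) -> dict[str, float]:
    """Per-dimension distance between two configurations, in span steps.

    Discrete spans contribute the absolute option-index difference;
    continuous spans contribute the absolute difference in units of one
    tenth of the span's range (a conventional "step" for an unquantized
    axis).  Augmentation dimensions are compared only when both
    configurations enable augmentation.
    """
    da, db = a.to_dict(), b.to_dict()
    aug_a = da.pop("augmentation", None)
    aug_b = db.pop("augmentation", None)
    steps: dict[str, float] = {}
    core_names = {
        "loss_function": "loss_function",
        "batch_size": "batch_size",
        "dropout": "dropout",
        "tl_learn_ratio": "tl_learn_ratio",
        "parameter_optimizer": "parameter_optimizer",
        "scaling_technique": "scaling_technique",
        "apply_augmentation": "apply_augmentation",
    }
    for key, span_name in core_names.items():
        span = space.span(span_name)
        va, vb = da[key], db[key]
        if span.is_discrete:
            steps[key] = abs(_element_index(va, span) - _element_index(vb, span))
        else:
            lo, hi = span.bounds
            steps[key] = abs(va - vb) / ((hi - lo) / 10.0)
    if aug_a is not None and aug_b is not None and space.includes_augmentation:
        for key in ("rotation_deg", "width_shift", "height_shift", "shear", "zoom"):
            span_name = "rotation" if key == "rotation_deg" else key
            span = space.span(span_name)
            if span.is_discrete:
                steps[key] = abs(aug_a[key] - aug_b[key]) / span.step
            else:
                lo, hi = span.bounds
                steps[key] = abs(aug_a[key] - aug_b[key]) / ((hi - lo) / 10.0)
        for key in ("horizontal_flip", "vertical_flip"):
            steps[key] = float(aug_a[key] != aug_b[key])
    return steps
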