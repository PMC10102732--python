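"""Stimulus schedules s(t) driving the recognition dynamics.

Four kinds are supported: ``null`` (s = 0, spontaneous dynamics),
``constant`` (static sensory input), ``sigmoid`` (logistic onset
``s(t) = s_inf / (1 + exp(-k (t - t_m)))``) and ``series`` (a sampled
time course with linear interpolation).  Stimuli are complex-valued for
generality; the published experiments use real values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Stimulus"]

# exp underflow guard: exp(x) for x < -_EXP_CLIP is treated as exactly 0
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class Stimulus:
    """A sensory schedule s(t).

    Use the constructors :meth:`null`, :meth:`constant`, :meth:`sigmoid`
    and :meth:`series` rather than the raw dataclass fields.
    """

    kind: str = "null"
    value: complex = 0j
    s_inf: complex = 0j
    k: float = 1.0
    t_m: float = 0.0
    series_t: Optional[np.ndarray] = field(default=None, repr=False)
    series_v: Optional[np.ndarray] = field(default=None, repr=False)
    extrapolate: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("null", "constant", "sigmoid", "series"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "sigmoid" and not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"sigmoid stiffness k must be positive, got {self.k!r}")
        if self.kind == "series":
            t = np.asarray(self.series_t, dtype=float)
            if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
                raise ValueError("series times must be strictly increasing, length >= 2")

    # -- constructors -------------------------------------------------
    @classmethod
    def null(cls) -> "Stimulus":
        return cls(kind="null")

    @classmethod
    def constant(cls, value: complex) -> "Stimulus":
        return cls(kind="constant", value=complex(value))

    @classmethod
    def sigmoid(cls, s_inf: complex, k: float, t_m: float) -> "Stimulus":
        return cls(kind="sigmoid", s_inf=complex(s_inf), k=float(k), t_m=float(t_m))

    @classmethod
    def series(
        cls, times, values, extrapolate: bool = True
    ) -> "Stimulus":
        return cls(
            kind="series",
            series_t=np.asarray(times, dtype=float),
            series_v=np.asarray(values, dtype=complex),
            extrapolate=extrapolate,
        )

    # -- evaluation ---------------------------------------------------
    def __call__(self, t: float) -> complex:
        """Evaluate s(t) at a single (finite) time."""
        if not math.isfinite(t):
            raise ValueError(f"stimulus time must be finite, got {t!r}")
        if self.kind == "null":
            return 0j
        if self.kind == "constant":
            return self.value
        if self.kind == "sigmoid":
            x = self.k * (t - self.t_m)
            if x < -_EXP_CLIP:
                return 0j
            if x > _EXP_CLIP:
                return self.s_inf
            return self.s_inf / (1.0 + math.exp(-x))
        # series
        t0, t1 = self.series_t[0], self.series_t[-1]
        if (t < t0 or t > t1) and not self.extrapolate:
            raise ValueError(f"time {t} outside series support [{t0}, {t1}]")
        tc = min(max(t, t0), t1)  # constant extrapolation at the ends
        re = np.interp(tc, self.series_t, self.series_v.real)
        im = np.interp(tc, self.series_t, self.series_v.imag)
        return complex(re, im)

    def sample(self, times) -> np.ndarray:
        """Vectorised evaluation on an array of times."""
        times = np.asarray(times, dtype=float)
        if self.kind == "null":
            return np.zeros(times.shape, dtype=complex)
        if self.kind == "constant":
            return np.full(times.shape, self.value, dtype=complex)
        if self.kind == "sigmoid":
            x = np.clip(self.k * (times - self.t_m), -_EXP_CLIP, _EXP_CLIP)
            out = self.s_inf / (1.0 + np.exp(-x))
            out[self.k * (times - self.t_m) < -_EXP_CLIP] = 0j
            return out.astype(complex)
        return np.array([self(t) for t in times], dtype=complex)

    @property
    def is_static(self) -> bool:
        """True when s(t) is independent of time."""
        return self.kind in ("null", "constant")

    def static_value(self) -> complex:
        if not self.is_static:
            raise ValueError("stimulus is time dependent")
        return 0j if self.kind == "null" else self.value
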