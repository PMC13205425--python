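"""Sine-carrier Gabor kernels and the mu/sigma texture feature vector.

A multi-scale Gabor filter bank (MS-GFB) is an ordered set of filters, each
described by six parameters: an ``m``-by-``m`` convolution window, a Gaussian
envelope of scale ``sigma`` and aspect ratio ``gamma``, a carrier orientation
``theta``, a carrier wavelength ``lam`` (pixels per cycle) and a phase offset
``psi``.  Each kernel is

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) * sin(2 pi x' / lam + psi)

with rotated coordinates x' = x cos(theta) + y sin(theta) and
y' = -x sin(theta) + y cos(theta); ``x`` indexes rows and ``y`` columns.  The
carrier is a *sine*, so an odd window with psi = 0 yields an exactly zero-sum,
point-antisymmetric kernel.

The descriptor of an image is the vector [mu_1, sigma_1, ..., mu_Nf, sigma_Nf]
where mu_j and sigma_j are the mean and population standard deviation of the
j-th filter response over all image pixels.

Kernels are synthesized directly from the formula above rather than delegated
to a library Gabor routine, because the common library convention (cosine
carrier, frequency-normalised envelope) differs from this parameterisation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
import numpy as np
from scipy.signal import convolve

__all__ = [
    "PARAM_ORDER",
    "PARAM_DOMAINS",
    "GaborParams",
    "GaborBank",
    "synthesize_kernel",
    "convolve_response",
    "response_statistics",
    "extract_feature_vector",
    "load_reference_bank",
]

#: canonical order of the six per-filter parameters inside a decision vector
PARAM_ORDER = ("m", "sigma", "theta", "lam", "gamma", "psi")

#: search domain for each parameter: window size in pixels, envelope scale in
#: pixels, orientation in radians, wavelength in pixels/cycle, aspect ratio
#: (dimensionless), phase in radians
PARAM_DOMAINS = {
    "m": (1.0, 20.0),
    "sigma": (1.0, 5.0),
    "theta": (0.0, math.pi),
    "lam": (1.0, 10.0),
    "gamma": (0.0, 1.0),
    "psi": (0.0, 2.0 * math.pi),
}


@dataclass(frozen=True)
class GaborParams:
    """One filter's six parameters; validated against the search domains."""

    m: int
    sigma: float
    theta: float
    lam: float
    gamma: float
    psi: float

    def __post_init__(self) -> None:
        if not float(self.m).is_integer():
            raise ValueError(f"window size m must be an integer, got {self.m}")
        object.__setattr__(self, "m", int(self.m))
        for name in ("sigma", "theta", "lam", "gamma", "psi"):
            object.__setattr__(self, name, float(getattr(self, name)))
        for name in PARAM_ORDER:
            lo, hi = PARAM_DOMAINS[name]
            value = getattr(self, name)
            if not (lo <= value <= hi) or not math.isfinite(value):
                raise ValueError(
                    f"parameter {name}={value!r} outside its domain [{lo}, {hi}]"
                )

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "sigma": self.sigma,
            "theta": self.theta,
            "lambda": self.lam,
            "gamma": self.gamma,
            "psi": self.psi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaborParams":
        return cls(
            m=d["m"],
            sigma=d["sigma"],
            theta=d["theta"],
            lam=d.get("lambda", d.get("lam")),
            gamma=d["gamma"],
            psi=d["psi"],
        )


@dataclass(frozen=True)
class GaborBank:
    """Ordered multi-scale bank of Gabor filters."""

    filters: tuple[GaborParams, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "filters", tuple(self.filters))
        if len(self.filters) < 1:
            raise ValueError("a bank needs at least one filter")

    def __len__(self) -> int:
        return len(self.filters)

    def __iter__(self):
        return iter(self.filters)

    def to_json(self) -> str:
        return json.dumps({"filters": [p.to_dict() for p in self.filters]}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GaborBank":
        payload = json.loads(text)
        return cls(tuple(GaborParams.from_dict(d) for d in payload["filters"]))


def _grid_offsets(m: int) -> np.ndarray:
    # integer offsets for odd m, symmetric half-integers for even m, so the
    # sampling grid is always centred on the origin
    return np.arange(m, dtype=float) - (m - 1) / 2.0


def synthesize_kernel(p: GaborParams) -> np.ndarray:
    """Sample the Gabor formula on an m-by-m grid centred at the origin."""
    off = _grid_offsets(p.m)
    x = off[:, np.newaxis]  # row offset
    y = off[np.newaxis, :]  # column offset
    xr = x * math.cos(p.theta) + y * math.sin(p.theta)
    yr = -x * math.sin(p.theta) + y * math.cos(p.theta)
    envelope = np.exp(-(xr**2 + p.gamma**2 * yr**2) / (2.0 * p.sigma**2))
    carrier = np.sin(2.0 * math.pi * xr / p.lam + p.psi)
    return envelope * carrier


def convolve_response(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 2-D convolution (kernel flipped), same-size output, edge-replicated
    borders.

    Edge replication makes the constant-image/zero-sum-kernel identity exact:
    a flat image convolved with an odd, psi=0 kernel responds 0 everywhere.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    m, n = kernel.shape
    pad = ((m - 1) // 2, m // 2), ((n - 1) // 2, n // 2)
    padded = np.pad(img, pad, mode="edge")
    return convolve(padded, kernel, mode="valid", method="auto")


def response_statistics(response: np.ndarray) -> tuple[float, float]:
    """Mean and population (divisor M*N) standard deviation of a response."""
    response = np.asarray(response, dtype=float)
    if response.size == 0:
        raise ValueError("empty response")
    return float(response.mean()), float(response.std(ddof=0))


def extract_feature_vector(img: np.ndarray, bank: GaborBank) -> np.ndarray:
    """Descriptor [mu_1, sigma_1, ..., mu_Nf, sigma_Nf] in bank filter order."""
    features = np.empty(2 * len(bank), dtype=float)
    for j, params in enumerate(bank):
        mu, sd = response_statistics(convolve_response(img, synthesize_kernel(params)))
        features[2 * j] = mu
        features[2 * j + 1] = sd
    return features


def load_reference_bank(which: str = "median") -> GaborBank:
    """Load one of the bundled reference banks (``median``, ``best``,
    ``worst``) — descriptors produced by a 31-run optimization on the PH2
    dermoscopy dataset, shipped so feature extraction can be exercised without
    rerunning the search."""
    text = resources.files("evogmd.data").joinpath("reference_banks.json").read_text()
    banks = json.loads(text)
    if which not in banks:
        raise KeyError(f"unknown reference bank {which!r}; choose from {sorted(banks)}")
    return GaborBank(tuple(GaborParams.from_dict(d) for d in banks[which]["filters"]))
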