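"""Zero-mean beat-timing noise models.

Four families are supported, each parameterized so that the noise standard
deviation equals a target sigma (in milliseconds):

* ``gaussian``     — Normal(0, sigma)
* ``uniform``      — Uniform(-sqrt(3) sigma, +sqrt(3) sigma)
* ``triangular``   — Triangular(A=-sqrt(6) sigma, B=0, C=+sqrt(6) sigma)
* ``student_t``    — scaled Student t with nu = 3 (heavy tails)

For the Student t there are two conventions for the scale.  The *literal*
parameterization sets sigma_hat = sqrt((nu - 1) sigma^2 / nu), which for
nu = 3 yields a noise variance of nu sigma_hat^2 / (nu - 2) = 2 sigma^2,
i.e. an SD of sqrt(2) sigma.  The default ``variance_matched`` mode instead
uses sigma_hat = sigma sqrt((nu - 2) / nu) = sigma / sqrt(3) so that the
noise SD equals sigma like the other three families.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io import Tachogram

__all__ = ["NoiseSpec", "sample_noise", "perturb_beats", "interval_noise"]

logger = logging.getLogger(__name__)

FAMILIES = ("gaussian", "uniform", "triangular", "student_t")
T_NU = 3
_MAX_RETRIES = 100


@dataclass(frozen=True)
class NoiseSpec:
    """One noise family with target standard deviation ``sigma`` (ms).

    ``sigma == 0`` is the degenerate zero-noise case (all draws are exactly
    zero), used for zero-noise identity checks.
    """

    family: str
    sigma: float
    t_mode: str = "variance_matched"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.t_mode not in ("variance_matched", "literal_eq4"):
            raise ValueError(f"unknown t_mode {self.t_mode!r}")

    @property
    def t_scale(self) -> float:
        """Scale sigma_hat of the Student-t family for the selected mode."""
        if self.t_mode == "literal_eq4":
            return self.sigma * math.sqrt((T_NU - 1) / T_NU)
        return self.sigma * math.sqrt((T_NU - 2) / T_NU)


def _resolve_rng(spec: NoiseSpec, rng) -> np.random.Generator:
    if rng is not None:
        return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return np.random.default_rng(spec.seed)


def sample_noise(spec: NoiseSpec, n: int, rng=None) -> np.ndarray:
    """Draw ``n`` i.i.d. noise values in milliseconds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _resolve_rng(spec, rng)
    s = spec.sigma
    if s == 0.0:
        return np.zeros(n)
    if spec.family == "gaussian":
        return rng.normal(0.0, s, size=n)
    if spec.family == "uniform":
        half = math.sqrt(3.0) * s
        return rng.uniform(-half, half, size=n)
    if spec.family == "triangular":
        c = math.sqrt(6.0) * s
        return rng.triangular(-c, 0.0, c, size=n)
    # student_t
    return spec.t_scale * rng.standard_t(T_NU, size=n)


def perturb_beats(tachogram: Tachogram, spec: NoiseSpec, rng=None) -> Tachogram:
    """Add independent noise (ms) to every beat time and rebuild the RR series.

    The input tachogram is not modified.  Draws that would break beat-time
    monotonicity (a non-positive interval) are resampled, up to a bounded
    number of rounds, rather than clipped — clipping would distort the noise
    distribution.
    """
    rng = _resolve_rng(spec, rng)
    n = len(tachogram)
    eps_s = sample_noise(spec, n, rng) / 1000.0
    times = tachogram.beat_times + eps_s
    retries = 0
    for _ in range(_MAX_RETRIES):
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size == 0:
            break
        idx = np.unique(np.concatenate([bad, bad + 1]))
        retries += idx.size
        eps_s[idx] = sample_noise(spec, idx.size, rng) / 1000.0
        times = tachogram.beat_times + eps_s
    else:
        raise RuntimeError(
            "could not restore beat-time monotonicity after "
            f"{_MAX_RETRIES} resampling rounds (sigma={spec.sigma} ms)"
        )
    if retries:
        logger.debug(
            "perturb_beats: resampled %d draws to keep beat times monotone",
            retries,
        )
    return Tachogram.from_beat_times(times, tachogram.recording_id)


def interval_noise(clean: Tachogram, noisy: Tachogram) -> np.ndarray:
    """Element-wise RR difference noisy - clean, in ms."""
    if len(clean.rr) != len(noisy.rr):
        raise ValueError(
            f"length mismatch: {len(clean.rr)} vs {len(noisy.rr)} intervals"
        )
    return noisy.rr - clean.rr
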