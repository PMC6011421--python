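"""White-Gaussian noise injection for observations (SNR) and operator (HNR).

Observation noise follows the usual additive model: i.i.d. zero-mean Gaussian
samples with variance ``P_signal * 10**(-snr_db/10)``.

Transfer-operator noise ("HNR": transfer-matrix-to-noise ratio) is defined
over the matrix entries: ``10*log10(meansq(H) / meansq(perturbation))``.  Two
schemes preserve the operator's symmetry:

* ``generator`` (default): noise is added to the sampled impulse-response
  vector/patch — mirrored to stay an even sample — and the matrix is rebuilt,
  so the (block-)Toeplitz structure and exact symmetry both survive.  The
  realized perturbation is rescaled so the matrix-level HNR hits the request
  exactly.
* ``symmetrize``: a dense Gaussian matrix E is symmetrized, ``H + (E+E^T)/2``;
  only ``H = H^T`` survives, not Toeplitz structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, UndefinedSNRError
from .fields import ObservationField
from .model_core import TransferOperator

__all__ = ["NoiseSpec", "add_observation_noise", "add_transfer_noise"]


@dataclass(frozen=True)
class NoiseSpec:
    """Configuration block for a noise condition."""

    target: str = "observation"          # {"observation", "transfer"}
    level_db: float = np.inf             # SNR or HNR in dB; inf = noiseless
    mode: str = "generator"              # transfer only: {"generator", "symmetrize"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target not in ("observation", "transfer"):
            raise ConfigurationError(f"unknown noise target {self.target!r}")
        if self.mode not in ("generator", "symmetrize"):
            raise ConfigurationError(f"unknown transfer-noise mode {self.mode!r}")
        if not (self.level_db >= 0):
            raise ConfigurationError("level_db must be >= 0 dB (or inf)")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def add_observation_noise(obs: ObservationField, snr_db: float, rng) -> ObservationField:
    """Add white-Gaussian noise at the requested SNR (dB) to the observations."""
    if snr_db == np.inf:
        return ObservationField(obs.values.copy(), obs.grid)
    if not snr_db >= 0:
        raise ConfigurationError(f"snr_db must be >= 0 or inf, got {snr_db}")
    p_signal = float(np.mean(obs.values**2))
    if p_signal == 0.0:
        raise UndefinedSNRError("signal power is zero; SNR is undefined")
    sigma = np.sqrt(p_signal * 10.0 ** (-snr_db / 10.0))
    noise = _as_rng(rng).normal(0.0, sigma, size=obs.values.shape)
    return ObservationField(obs.values + noise, obs.grid)


def _even_noise_like(impulse: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw an even (mirror-symmetric) Gaussian sample over signed offsets."""
    if impulse.ndim == 1:
        n = (impulse.shape[0] + 1) // 2
        half = rng.standard_normal(n)            # offsets 0 .. n-1
        return np.concatenate([half[:0:-1], half])
    m = (impulse.shape[0] + 1) // 2
    full = rng.standard_normal(impulse.shape)
    center = m - 1
    # enforce e(d) = e(-d): keep the half-plane (rows below center, plus the
    # right half of the center row) and mirror it through the origin
    out = full.copy()
    out[:center, :] = full[:center:-1, ::-1]
    out[center, :center] = full[center, :center:-1]
    return out


def add_transfer_noise(T: TransferOperator, hnr_db: float, rng,
                       mode: str = "generator") -> TransferOperator:
    """Perturb the transfer operator at the requested HNR (dB).

    ``generator`` mode perturbs the impulse sample (kept even) and rebuilds;
    ``symmetrize`` mode adds a symmetrized dense matrix.  Both scale the
    realized perturbation so the matrix-entry mean-square ratio equals the
    request exactly.
    """
    if hnr_db == np.inf:
        return TransferOperator.from_impulse(T.impulse.copy(), T.grid, T.constants)
    if not hnr_db >= 0:
        raise ConfigurationError(f"hnr_db must be >= 0 or inf, got {hnr_db}")
    rng = _as_rng(rng)
    H = T.matrix
    target_msq = float(np.mean(H**2)) * 10.0 ** (-hnr_db / 10.0)
    if mode == "generator":
        e = _even_noise_like(T.impulse, rng)
        probe = TransferOperator.from_impulse(e, T.grid, T.constants)
        realized_msq = float(np.mean(probe.matrix**2))
        scale = np.sqrt(target_msq / realized_msq)
        return TransferOperator.from_impulse(T.impulse + scale * e, T.grid, T.constants)
    if mode == "symmetrize":
        E = rng.standard_normal(H.shape)
        E = 0.5 * (E + E.T)
        scale = np.sqrt(target_msq / float(np.mean(E**2)))
        out = TransferOperator.from_impulse(T.impulse.copy(), T.grid, T.constants)
        out.matrix = H + scale * E
        return out
    raise ConfigurationError(f"unknown transfer-noise mode {mode!r}")
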