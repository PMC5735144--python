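"""Interaction entropy: the entropic term -T*dS from interaction-energy fluctuations.

The interaction-entropy (IE) estimator replaces normal-mode analysis with an
exponential average over the fluctuations of the protein-ligand interaction
energy sampled along a trajectory:

    -T*dS = kT * ln < exp(beta * dE) >,   dE = E - <E>,   beta = 1/kT

where <.> is the arithmetic average over the N sampled frames.  Every frame
of the production window contributes, so the estimate needs no additional
computation beyond the per-frame interaction energies themselves.

Properties used heavily by the tests:

* Jensen's inequality makes the estimate nonnegative for every series.
* It is invariant under adding a constant to all energies (only
  fluctuations enter).
* For i.i.d. Gaussian fluctuations with standard deviation sigma the
  population value is exactly sigma^2 / (2 kT) (mean of a lognormal).

The exponential average is always evaluated in the log domain (max-shifted)
so that fluctuations of hundreds of kT cannot overflow.  Note that for
sigma well above ~2 kT the estimator converges extremely slowly (the
average is dominated by rare high-energy frames); a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .errors import EmptyInputError, ValidationError
from .io_formats import EnergySeries

BOLTZMANN_K = 0.0019872041  # kcal/(mol*K)


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and Boltzmann constant; kT = 0.59616 kcal/mol at 300 K."""

    temperature: float = 300.0
    boltzmann_k: float = BOLTZMANN_K

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0")

    @property
    def kt(self) -> float:
        return self.boltzmann_k * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kt


@dataclass(frozen=True)
class IEResult:
    mean_energy: float  # <E>, kcal/mol
    minus_t_delta_s: float  # -T*dS >= 0, kcal/mol
    n_samples: int
    running_mean_energy: np.ndarray
    running_entropy: np.ndarray
    block_sd: Optional[float] = None


def _select(series: EnergySeries, component: str) -> np.ndarray:
    try:
        return {"total": series.e_total, "ele": series.e_ele, "vdw": series.e_vdw}[component]
    except KeyError:
        raise ValidationError(f"unknown energy component: {component!r}") from None


def _ie_from_samples(x: np.ndarray, thermo: ThermoParams) -> tuple[float, float]:
    mean = float(np.mean(x))
    d = thermo.beta * (x - mean)
    # log <exp(d)> via max-shifted logsumexp: overflow-free for any |d|
    val = thermo.kt * float(logsumexp(d) - np.log(len(x)))
    return mean, max(val, 0.0)


def interaction_entropy(
    series: EnergySeries,
    thermo: ThermoParams = ThermoParams(),
    component: str = "total",
    n_blocks: Optional[int] = None,
) -> IEResult:
    """Full-series IE estimate with running-convergence diagnostics.

    Parameters
    ----------
    series : EnergySeries
        Per-frame interaction energies; the estimate uses ``component``
        (default the total interaction energy).
    thermo : ThermoParams
        Temperature and Boltzmann constant defining kT and beta.
    n_blocks : int, optional
        If given, also compute :func:`block_sd` over that many blocks.
    """
    x = np.asarray(_select(series, component), dtype=float)
    if len(x) == 0:
        raise EmptyInputError("empty energy series")
    if not np.all(np.isfinite(x)):
        raise ValidationError("energy series contains non-finite values")

    mean, ie = _ie_from_samples(x, thermo)
    sigma = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if sigma > 2.0 * thermo.kt:
        warnings.warn(
            f"energy fluctuation sd ({sigma:.2f} kcal/mol) exceeds 2 kT "
            f"({2 * thermo.kt:.2f}); the exponential average converges slowly "
            "and the IE estimate may be strongly sampling-dependent",
            RuntimeWarning,
            stacklevel=2,
        )
    run_mean, run_ie = running_arrays(x, thermo)
    bsd = block_sd(series, thermo, n_blocks, component=component) if n_blocks else None
    return IEResult(
        mean_energy=mean,
        minus_t_delta_s=ie,
        n_samples=len(x),
        running_mean_energy=run_mean,
        running_entropy=run_ie,
        block_sd=bsd,
    )


def running_arrays(x: np.ndarray, thermo: ThermoParams) -> tuple[np.ndarray, np.ndarray]:
    """Running <E> and -T*dS where element i uses samples 0..i inclusive.

    log sum_j<=i exp(beta*E_j) accumulates via logaddexp, so the running
    estimate is overflow-free too; the running mean is subtracted in the
    log domain afterwards.
    """
    n = len(x)
    counts = np.arange(1, n + 1)
    run_mean = np.cumsum(x) / counts
    log_acc = np.logaddexp.accumulate(thermo.beta * x)
    run_ie = thermo.kt * (log_acc - np.log(counts) - thermo.beta * run_mean)
    return run_mean, np.maximum(run_ie, 0.0)


def running_convergence(
    series: EnergySeries, thermo: ThermoParams = ThermoParams(), component: str = "total"
) -> tuple[np.ndarray, np.ndarray]:
    """Convergence traces of the mean interaction energy and the IE term."""
    x = np.asarray(_select(series, component), dtype=float)
    if len(x) == 0:
        raise EmptyInputError("empty energy series")
    return running_arrays(x, thermo)


def block_sd(
    series: EnergySeries,
    thermo: ThermoParams = ThermoParams(),
    n_blocks: int = 10,
    component: str = "total",
) -> float:
    """Sample SD (ddof=1) of per-block IE estimates over contiguous blocks.

    The series is cut into ``n_blocks`` equal-length blocks (remainder frames
    at the end dropped); each block gets its own mean, so a series that is
    constant within blocks has zero block SD.
    """
    x = np.asarray(_select(series, component), dtype=float)
    if n_blocks < 2:
        raise ValidationError("n_blocks must be >= 2")
    if len(x) < 2 * n_blocks:
        raise ValidationError(
            f"need at least {2 * n_blocks} samples for {n_blocks} blocks, got {len(x)}"
        )
    length = len(x) // n_blocks
    estimates = [
        _ie_from_samples(x[k * length : (k + 1) * length], thermo)[1]
        for k in range(n_blocks)
    ]
    return float(np.std(estimates, ddof=1))
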