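"""Parameter containers and the model-variant registry.

The latent dynamics of the internal position estimate follow a leaky,
gain-scaled, biased integrator driven by accumulating Gaussian noise
(an Ornstein-Uhlenbeck process).  Its four parameters can be expressed
per meter of travel (distance scaling) or per second (time scaling).
Reports of the homing vector are corrupted by reporting noise that is
either Weber-like (log-normal in distance) or of constant magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

NoiseMode = Literal["accumulate_distance", "accumulate_time", "constant"]
ReportMode = Literal["weber", "constant", "none"]
FitLevel = Literal["participant", "group"]

__all__ = [
    "IntegratorParams",
    "ReportParams",
    "VariantSpec",
    "VARIANTS",
    "get_variant",
    "count_params",
    "rescale_params",
    "unrescale_params",
]


@dataclass(frozen=True)
class IntegratorParams:
    """Leaky-integrator parameters.

    beta
        Memory decay (leak) rate; per meter in distance scaling, per
        second in time scaling.  ``beta = 0`` is a perfect integrator.
    alpha
        Multiplicative velocity gain; 1 is unbiased displacement.
    bias
        Additive bias vector, pulling the estimate in a fixed world
        direction per meter (or per second) of travel.
    sigma0_sq
        Accumulating-noise variance rate, m^2 per meter (or per second);
        in constant-noise variants this is the fixed per-stop variance
        in m^2.
    """

    beta: float = 0.0
    alpha: float = 1.0
    bias: tuple[float, float] = (0.0, 0.0)
    sigma0_sq: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.beta, self.alpha, *self.bias, self.sigma0_sq)
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite integrator parameters: {self}")
        if self.beta < 0:
            raise ValueError("leak rate beta must be >= 0")
        if self.sigma0_sq < 0:
            raise ValueError("noise variance sigma0_sq must be >= 0")

    @property
    def bias_vec(self) -> np.ndarray:
        return np.asarray(self.bias, dtype=float)


@dataclass(frozen=True)
class ReportParams:
    """Reporting-noise parameters.

    sigma_d_sq
        Distance reporting-noise variance: of ``log d_hat`` in Weber
        mode (dimensionless), of ``d_hat`` in constant mode (m^2).
    sigma_phi_sq
        Angular reporting-noise variance, rad^2.
    """

    sigma_d_sq: float = 0.0
    sigma_phi_sq: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_d_sq) or not np.isfinite(self.sigma_phi_sq):
            raise ValueError("non-finite reporting-noise parameters")
        if self.sigma_d_sq < 0 or self.sigma_phi_sq < 0:
            raise ValueError("reporting-noise variances must be >= 0")


@dataclass(frozen=True)
class VariantSpec:
    """A named model variant: noise mode x report mode x bias toggle."""

    name: str
    noise_mode: NoiseMode = "accumulate_distance"
    report_mode: ReportMode = "weber"
    additive_bias_enabled: bool = True
    fit_level: FitLevel = "participant"

    @property
    def n_integrator_params(self) -> int:
        # beta, alpha, sigma0_sq always free; bias adds (bx, by)
        return 3 + (2 if self.additive_bias_enabled else 0)

    @property
    def n_report_params(self) -> int:
        return 0 if self.report_mode == "none" else 2

    def with_fit_level(self, fit_level: FitLevel) -> "VariantSpec":
        return replace(self, fit_level=fit_level)


def _v(name, noise, report, bias):
    return VariantSpec(name=name, noise_mode=noise, report_mode=report,
                       additive_bias_enabled=bias)


#: The eight named variants of the error-decomposition analysis.
VARIANTS: dict[str, VariantSpec] = {
    v.name: v
    for v in [
        _v("full", "accumulate_distance", "weber", True),
        _v("full-RN", "accumulate_distance", "none", True),
        _v("full-AB-RN", "accumulate_distance", "none", False),
        _v("full-AN+CN-AB-RN", "constant", "none", False),
        _v("full-AN+CN-RN", "constant", "none", True),
        _v("full-AN+CN", "constant", "weber", True),
        _v("full-RN+CRN", "accumulate_distance", "constant", True),
        _v("time", "accumulate_time", "weber", True),
    ]
}


def get_variant(variant: "str | VariantSpec") -> VariantSpec:
    if isinstance(variant, VariantSpec):
        return variant
    try:
        return VARIANTS[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; known: {sorted(VARIANTS)}"
        ) from None


def count_params(variant: "str | VariantSpec", fit_level: FitLevel | None = None,
                 n_participants: int = 1) -> int:
    """Number of free parameters k entering the BIC penalty.

    Per participant the count is 7 for full-type variants (beta, alpha,
    bias x/y, sigma0_sq, sigma_d_sq, sigma_phi_sq), 5 without reporting
    noise, 3 without reporting noise and additive bias.  Individually
    fitted cohorts multiply by the number of participants; a group-level
    fit shares one set.
    """
    spec = get_variant(variant)
    level = fit_level if fit_level is not None else spec.fit_level
    per = spec.n_integrator_params + spec.n_report_params
    if level == "group":
        return per
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    return per * n_participants


def rescale_params(params: IntegratorParams, speed: float) -> IntegratorParams:
    """Convert time-scaled parameters to distance scaling at walking speed |v|.

    beta_tilde = beta/|v|, b_tilde = b/|v|, sigma0_sq_tilde = sigma0_sq/|v|;
    the gain alpha is scale-free.
    """
    if not speed > 0:
        raise ValueError("walking speed must be > 0")
    return IntegratorParams(
        beta=params.beta / speed,
        alpha=params.alpha,
        bias=(params.bias[0] / speed, params.bias[1] / speed),
        sigma0_sq=params.sigma0_sq / speed,
    )


def unrescale_params(params: IntegratorParams, speed: float) -> IntegratorParams:
    """Inverse of :func:`rescale_params`."""
    if not speed > 0:
        raise ValueError("walking speed must be > 0")
    return IntegratorParams(
        beta=params.beta * speed,
        alpha=params.alpha,
        bias=(params.bias[0] * speed, params.bias[1] * speed),
        sigma0_sq=params.sigma0_sq * speed,
    )
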