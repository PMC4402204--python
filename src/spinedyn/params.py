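"""Model parameters and their validation.

The parameter set collects every constant of the daily weight-update model:
thresholds for silencing and for counting a synapse as "strong", the bounds of
the weight-dependent volatility factor, the cluster-coupled LTP amplitude
range, the LTD amplitude, the LTP saturation constants, and the regeneration
probability ceiling.  Defaults are the standard values used throughout the
simulations; variant switches select the fixed-LTP-amplitude model, the model
without regeneration, or the exponential-increment model.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ModelParams", "VARIANTS", "ParamError"]

VARIANTS = ("standard", "fixed_ltp", "no_regeneration", "exponential_increments")


class ParamError(ValueError):
    """Raised when a parameter value or combination is invalid."""


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of the clustered synaptic-weight model.

    Attributes
    ----------
    N_cl:
        Number of synapses per cluster (chain topology).
    W_reset:
        Weight assigned to a synapse on regeneration.
    W_sil:
        Basal weight of a silent synapse.
    T_wk:
        Silencing threshold: an active synapse whose updated weight falls
        below ``T_wk`` is reset to silent.
    T_st:
        Strong-synapse threshold: a synapse with ``W > T_st`` counts toward
        the per-cluster strong count ``N_st``.
    v_hi, v_lo:
        Upper and lower bounds of the volatility factor (at ``W = 0`` and
        ``W >> W_med`` respectively).
    W_med:
        Half-saturation weight of the volatility factor.
    x1, x2:
        Minimum and maximum mean LTP amplitude; the per-cluster mean LTP
        amplitude interpolates linearly between them as ``N_st`` grows.
    a2:
        Mean LTD amplitude.
    sd_ratio:
        Fixed ratio of increment mean to increment standard deviation for the
        Gaussian draws (means are 4x the standard deviations by default).
    k_hi, W_hi:
        LTP saturation parameters; the LTP amplitude carries a factor
        ``1 - k_hi * W / (W + W_hi)``.
    P_bas:
        Maximal per-day regeneration probability of a silent synapse.
    variant:
        One of ``standard``, ``fixed_ltp``, ``no_regeneration``,
        ``exponential_increments``.
    a1_fixed, sd1_fixed:
        Mean and sd of the LTP increment in the ``fixed_ltp`` variant
        (cluster coupling of the LTP amplitude removed).
    lambda1, lambda2:
        Decay rate constants of the LTP/LTD increment densities in the
        ``exponential_increments`` variant (density proportional to
        ``exp(-lambda * r)``; mean increment ``1 / lambda``).
    """

    N_cl: int = 10
    W_reset: float = 0.4
    W_sil: float = 0.05
    T_wk: float = 0.08
    T_st: float = 0.8
    v_hi: float = 4.0
    v_lo: float = 0.2
    W_med: float = 0.4
    x1: float = 0.144
    x2: float = 0.18
    a2: float = 0.16
    sd_ratio: float = 4.0
    k_hi: float = 0.05
    W_hi: float = 20.0
    P_bas: float = 0.1
    variant: str = "standard"
    a1_fixed: float = 0.16
    sd1_fixed: float = 0.04
    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParamError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )
        if not (0 < self.W_sil < self.T_wk < self.T_st):
            raise ParamError(
                "thresholds must satisfy 0 < W_sil < T_wk < T_st "
                f"(got W_sil={self.W_sil}, T_wk={self.T_wk}, T_st={self.T_st})"
            )
        if not (0 < self.x1 <= self.x2):
            raise ParamError(f"need 0 < x1 <= x2 (got x1={self.x1}, x2={self.x2})")
        if not (0 < self.v_lo < self.v_hi):
            raise ParamError(
                f"need 0 < v_lo < v_hi (got v_lo={self.v_lo}, v_hi={self.v_hi})"
            )
        if self.W_med <= 0:
            raise ParamError(f"W_med must be positive (got {self.W_med})")
        if self.W_hi <= 0:
            raise ParamError(f"W_hi must be positive (got {self.W_hi})")
        if not (0 <= self.k_hi < 1):
            raise ParamError(f"need 0 <= k_hi < 1 (got {self.k_hi})")
        if not (0 <= self.P_bas <= 1):
            raise ParamError(f"P_bas must lie in [0, 1] (got {self.P_bas})")
        if self.N_cl < 2:
            raise ParamError(f"N_cl must be at least 2 (got {self.N_cl})")
        if self.sd_ratio <= 0:
            raise ParamError(f"sd_ratio must be positive (got {self.sd_ratio})")
        if self.W_reset <= self.T_wk:
            raise ParamError(
                f"W_reset must exceed T_wk (got W_reset={self.W_reset}, T_wk={self.T_wk})"
            )
        if self.a2 <= 0:
            raise ParamError(f"a2 must be positive (got {self.a2})")
        if self.a1_fixed <= 0 or self.sd1_fixed <= 0:
            raise ParamError("a1_fixed and sd1_fixed must be positive")
        for name in ("lambda1", "lambda2"):
            lam = getattr(self, name)
            if not (0.5 <= lam <= 3.0):
                raise ParamError(f"{name} must lie in [0.5, 3.0] (got {lam})")

    # -- convenience -----------------------------------------------------

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def scaled_ltp(self, factor: float) -> "ModelParams":
        """Return a copy with the mean LTP amplitude scaled by ``factor``.

        In the standard model both ``x1`` and ``x2`` are scaled; in the
        ``fixed_ltp`` variant ``a1_fixed`` and ``sd1_fixed`` are scaled so the
        mean/sd ratio is preserved.
        """
        if factor <= 0:
            raise ParamError(f"LTP scale factor must be positive (got {factor})")
        if self.variant == "fixed_ltp":
            return self.replace(
                a1_fixed=self.a1_fixed * factor, sd1_fixed=self.sd1_fixed * factor
            )
        return self.replace(x1=self.x1 * factor, x2=self.x2 * factor)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ModelParams":
        """Build from a flat mapping; unknown keys are an error."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParamError(f"unknown parameter key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ParamError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(data)
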