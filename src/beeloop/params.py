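"""Behavioural parameters of the central-place persistent turning walker.

The walker flies at constant speed ``v`` while its signed turning rate
(angular speed, rad/s) relaxes towards a target value under an
Ornstein-Uhlenbeck process with autocorrelation ``gamma`` (1/s) and noise
amplitude ``sigma`` (rad/s^(1/2), as conventionally printed).  Two derived
re-parameterizations are used for fitting: the stationary angular-speed
variance ``Omega = sigma^2 / (2 gamma)`` and the mean exploration duration
``alpha = 1 / p_return``.  Both must round-trip exactly with the native
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields


@dataclass(frozen=True)
class ModelParams:
    """The four behavioural parameters plus kinematic and bookkeeping knobs.

    Defaults are the calibrated population-level values for *Bombus
    terrestris* exploration flights: ``gamma`` = 1.0 1/s, ``sigma`` = 0.37
    rad/s^(1/2) (so Omega ~ 0.07 rad^2/s^2), ``p_return`` = 1/30 1/s
    (alpha = 30 s), ``eta_star`` = 0.2 1/s.  Flight speed is not observable
    from the calibration observables and defaults to 5 m/s.
    """

    gamma: float = 1.0            # OU autocorrelation coefficient, 1/s
    sigma: float = 0.37           # OU noise amplitude, rad/s^(1/2)
    p_return: float = 1.0 / 30.0  # switch probability per unit time, 1/s
    eta_star: float = 0.2         # homing attraction strength, 1/s
    speed: float = 5.0            # constant flight speed v, m/s
    dt: float = 0.01              # integration step, s
    nest_radius: float = 13.0     # loop-termination radius around the nest, m
    max_loop_duration: float = 3600.0  # censoring cap per loop, s

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not self.p_return > 0:
            raise ValueError(f"p_return must be > 0, got {self.p_return}")
        if self.eta_star < 0:
            raise ValueError(f"eta_star must be >= 0, got {self.eta_star}")
        if not self.speed > 0:
            raise ValueError(f"speed must be > 0, got {self.speed}")
        if not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not self.nest_radius > 0:
            raise ValueError(f"nest_radius must be > 0, got {self.nest_radius}")
        if not self.max_loop_duration > 0:
            raise ValueError("max_loop_duration must be > 0")

    @property
    def omega_var(self) -> float:
        """Stationary variance of the angular speed, Omega = sigma^2/(2 gamma)."""
        return self.sigma * self.sigma / (2.0 * self.gamma)

    @property
    def alpha(self) -> float:
        """Mean duration of the exploration phase, alpha = 1/p_return, s."""
        return 1.0 / self.p_return

    @classmethod
    def from_omega_alpha(
        cls,
        gamma: float,
        omega_var: float,
        alpha: float,
        eta_star: float,
        **kwargs: float,
    ) -> "ModelParams":
        """Build from the fitting parameterization (gamma, Omega, alpha, eta*)."""
        if omega_var < 0:
            raise ValueError(f"omega_var must be >= 0, got {omega_var}")
        if not alpha > 0:
            raise ValueError(f"alpha must be > 0, got {alpha}")
        return cls(
            gamma=gamma,
            sigma=math.sqrt(2.0 * gamma * omega_var),
            p_return=1.0 / alpha,
            eta_star=eta_star,
            **kwargs,
        )

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)

    # -- flat-dict serialization (config files) -----------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        """Build from a flat mapping; accepts ``omega_var`` in place of
        ``sigma`` and ``alpha`` in place of ``p_return``.  Unknown keys are
        rejected."""
        d = dict(d)
        known = {f.name for f in fields(cls)} | {"omega_var", "alpha"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        if "omega_var" in d:
            if "sigma" in d:
                raise ValueError("give either sigma or omega_var, not both")
            gamma = d.get("gamma", cls.gamma)
            d["sigma"] = math.sqrt(2.0 * gamma * d.pop("omega_var"))
        if "alpha" in d:
            if "p_return" in d:
                raise ValueError("give either p_return or alpha, not both")
            d["p_return"] = 1.0 / d.pop("alpha")
        return cls(**d)
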