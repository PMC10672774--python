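"""Deterministic core of the probit-binomial effect model.

A latent, log-scale "concentration" decays linearly in time from a fixed
intercept of 100 with slope -1; co-administered vasoconstrictor rescales the
slope by (1 - adr).  The probability of reacting to a stimulus is the upper
normal tail of that latent variable around a drug/individual-specific
transition (mu, sigma), and the observed score out of ``n_stim`` stimulations
is binomial in that probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtr

__all__ = [
    "INTERCEPT",
    "SLOPE",
    "N_STIM",
    "N_DRUGS",
    "DRUG_NAMES",
    "ARM_LABELS",
    "Arm",
    "DrugCurveParams",
    "PopulationParams",
    "latent_concentration",
    "reaction_probability",
    "half_effect_time",
    "score_pmf",
]

#: Fixed identifiability anchors of the latent decay (see module docstring).
INTERCEPT: float = 100.0
SLOPE: float = -1.0

#: Default number of needle stimulations per time point (score range 0..N_STIM).
N_STIM: int = 6

N_DRUGS: int = 4

#: 1-based drug indices as used throughout the study design.
DRUG_NAMES: dict[int, str] = {1: "Pro", 2: "Lid", 3: "Mep", 4: "Bup"}

#: The five study arms: four plain drugs plus lidocaine with adrenaline.
ARM_LABELS: dict[str, tuple[int, int]] = {
    "Pro": (1, 0),
    "Lid": (2, 0),
    "Mep": (3, 0),
    "Bup": (4, 0),
    "Lid+Adr": (2, 1),
}


@dataclass(frozen=True)
class Arm:
    """One experimental arm: a drug plus an adrenaline indicator.

    Parameters
    ----------
    drug_index
        1-based drug index in {1, 2, 3, 4} (Pro, Lid, Mep, Bup).
    v_adr
        Adrenaline dummy: 0 absent, 1 present.  The bundled study layout
        uses v_adr=1 only with lidocaine, which shares the plain-lidocaine
        drug parameters; any combination is accepted here.
    """

    drug_index: int
    v_adr: int = 0

    def __post_init__(self) -> None:
        if self.drug_index not in DRUG_NAMES:
            raise ValueError(
                f"drug_index must be one of {sorted(DRUG_NAMES)}, got {self.drug_index}"
            )
        if self.v_adr not in (0, 1):
            raise ValueError(f"v_adr must be 0 or 1, got {self.v_adr}")

    @property
    def label(self) -> str:
        name = DRUG_NAMES[self.drug_index]
        return f"{name}+Adr" if self.v_adr else name

    @classmethod
    def from_label(cls, label: str) -> "Arm":
        try:
            drug_index, v_adr = ARM_LABELS[label]
        except KeyError:
            raise ValueError(
                f"unknown arm label {label!r}; expected one of {sorted(ARM_LABELS)}"
            ) from None
        return cls(drug_index=drug_index, v_adr=v_adr)


@dataclass(frozen=True)
class DrugCurveParams:
    """Transition parameters of one probability curve.

    ``mu`` locates the probit transition on the latent-concentration scale,
    ``sigma`` is its spread, and ``adr_effect`` is the precomputed product
    adr * v_adr in [0, 1).
    """

    mu: float
    sigma: float
    adr_effect: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.adr_effect < 1.0:
            raise ValueError(f"adr_effect must be in [0, 1), got {self.adr_effect}")


@dataclass(frozen=True, eq=False)
class PopulationParams:
    """Per-drug hyperparameters plus the global adrenaline effect and offset SD.

    Arrays are indexed by drug (length 4, order Pro, Lid, Mep, Bup).
    ``sigma0`` (the natural-scale spread location) is ``exp(log_sigma0)``.
    """

    mu0: np.ndarray
    s_mu0: np.ndarray
    log_sigma0: np.ndarray
    log_s_sigma0: np.ndarray
    adr: float
    sd_d: float = 0.0
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for attr in ("mu0", "s_mu0", "log_sigma0", "log_s_sigma0"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (N_DRUGS,):
                raise ValueError(f"{attr} must have shape ({N_DRUGS},), got {arr.shape}")
            object.__setattr__(self, attr, arr)
        if np.any(self.s_mu0 < 0):
            raise ValueError("s_mu0 must be >= 0")
        if np.any(self.log_s_sigma0 < 0):
            raise ValueError("log_s_sigma0 must be >= 0")
        if not 0.0 <= self.adr <= 1.0:
            raise ValueError(f"adr must be in [0, 1], got {self.adr}")
        if self.sd_d < 0:
            raise ValueError(f"sd_d must be >= 0, got {self.sd_d}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, PopulationParams):
            return NotImplemented
        return (
            np.array_equal(self.mu0, other.mu0)
            and np.array_equal(self.s_mu0, other.s_mu0)
            and np.array_equal(self.log_sigma0, other.log_sigma0)
            and np.array_equal(self.log_s_sigma0, other.log_s_sigma0)
            and self.adr == other.adr
            and self.sd_d == other.sd_d
        )

    @property
    def sigma0(self) -> np.ndarray:
        return np.exp(self.log_sigma0)

    def to_dict(self) -> dict:
        return {
            "mu0": self.mu0.tolist(),
            "s_mu0": self.s_mu0.tolist(),
            "log_sigma0": self.log_sigma0.tolist(),
            "log_s_sigma0": self.log_s_sigma0.tolist(),
            "adr": self.adr,
            "sd_d": self.sd_d,
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParams":
        return cls(
            mu0=np.asarray(d["mu0"], dtype=float),
            s_mu0=np.asarray(d["s_mu0"], dtype=float),
            log_sigma0=np.asarray(d["log_sigma0"], dtype=float),
            log_s_sigma0=np.asarray(d["log_s_sigma0"], dtype=float),
            adr=float(d["adr"]),
            sd_d=float(d.get("sd_d", 0.0)),
            name=str(d.get("name", "")),
        )


def _check_adr_effect(adr_effect) -> np.ndarray:
    a = np.asarray(adr_effect, dtype=float)
    if np.any(a < 0.0) or np.any(a >= 1.0):
        raise ValueError(f"adr_effect must be in [0, 1), got {adr_effect}")
    return a


def latent_concentration(t, adr_effect=0.0):
    """Latent log-scale concentration at time ``t`` minutes.

    Returns ``100 - (1 - adr_effect) * t``: strictly decreasing in ``t``
    (negative values are permitted and push the reaction probability toward 1).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    a = _check_adr_effect(adr_effect)
    out = INTERCEPT + SLOPE * (1.0 - a) * t
    return float(out) if out.ndim == 0 else out


def reaction_probability(t, params: DrugCurveParams):
    """Probability of reacting to one stimulus at time ``t``.

    The upper normal tail ``1 - Phi((C(t) - mu) / sigma)``; nondecreasing
    in ``t`` for ``adr_effect < 1``.
    """
    c = latent_concentration(t, params.adr_effect)
    z = (np.asarray(c, dtype=float) - params.mu) / params.sigma
    out = ndtr(-z)  # 1 - Phi(z), computed without cancellation
    return float(out) if out.ndim == 0 else out


def half_effect_time(mu: float, adr_effect: float = 0.0) -> float:
    """Time at which the reaction probability is exactly 0.5.

    Inverting the latent decay gives ``(100 - mu) / (1 - adr_effect)``;
    without adrenaline this is simply ``100 - mu``.
    """
    a = float(_check_adr_effect(adr_effect))
    return (INTERCEPT - mu) / (1.0 - a)


def score_pmf(p: float, n_stim: int = N_STIM) -> np.ndarray:
    """Binomial(n_stim, p) mass function over scores 0..n_stim (sums to 1)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    out = np.zeros(n_stim + 1)
    if p == 0.0:
        out[0] = 1.0
    elif p == 1.0:
        out[-1] = 1.0
    else:
        # log space avoids under/overflow for extreme but nonzero p
        k = np.arange(n_stim + 1)
        log_coef = (
            stats.binom.logpmf(k, n_stim, 0.5) + n_stim * np.log(2.0)
        )
        out = np.exp(log_coef + k * np.log(p) + (n_stim - k) * np.log1p(-p))
        out /= out.sum()
    return out
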