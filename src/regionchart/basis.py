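"""Fractional-polynomial design bases over age, sex and eTIV.

Age enters through ``t = log(age + c)`` with a small offset ``c`` (default
0.75 years, roughly gestation) so the basis is defined from birth.
A fractional-polynomial term with power p contributes t^p, with the
conventional p = 0 -> log(t).  The location predictor always carries an
intercept and a male indicator; volume regions additionally carry a
centred log(eTIV) column.  Scale uses its own (shorter) power set and
shape is a constant unless a power is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: allowed fractional-polynomial powers (0 denotes log)
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

#: default centring constant for log eTIV (mm^3), ~ a typical adult head
DEFAULT_ETIV_CENTER = float(np.log(1.5e6))


@dataclass(frozen=True)
class BasisSpec:
    """Design specification for one region's (mu, sigma, nu) predictors."""

    mu_powers: tuple[float, ...] = (1.0, 2.0)
    sigma_powers: tuple[float, ...] = (1.0,)
    nu_powers: tuple[float, ...] = ()          # empty -> constant shape
    include_etiv: bool = False                 # volumes only
    age_offset: float = 0.75                   # years; c in t = log(age + c)
    etiv_center: float = DEFAULT_ETIV_CENTER

    def __post_init__(self) -> None:
        for label, powers, cap in (
            ("mu", self.mu_powers, 3),
            ("sigma", self.sigma_powers, 2),
            ("nu", self.nu_powers, 1),
        ):
            if len(powers) > cap:
                raise ValueError(f"{label} basis allows at most {cap} powers")
            if len(set(powers)) != len(powers):
                raise ValueError(f"duplicate {label} powers: {powers}")
            bad = [p for p in powers if p not in FP_POWERS]
            if bad:
                raise ValueError(f"powers {bad} not in allowed set {FP_POWERS}")
        if self.age_offset <= 0:
            raise ValueError("age offset c must be strictly positive")

    @property
    def mu_columns(self) -> list[str]:
        cols = ["intercept"] + [_power_name(p) for p in self.mu_powers] + ["male"]
        if self.include_etiv:
            cols.append("log_etiv_c")
        return cols

    @property
    def sigma_columns(self) -> list[str]:
        return ["intercept"] + [_power_name(p) for p in self.sigma_powers]

    @property
    def nu_columns(self) -> list[str]:
        return ["intercept"] + [_power_name(p) for p in self.nu_powers]

    def to_dict(self) -> dict:
        return {
            "mu_powers": list(self.mu_powers),
            "sigma_powers": list(self.sigma_powers),
            "nu_powers": list(self.nu_powers),
            "include_etiv": self.include_etiv,
            "age_offset": self.age_offset,
            "etiv_center": self.etiv_center,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(
            mu_powers=tuple(d["mu_powers"]),
            sigma_powers=tuple(d["sigma_powers"]),
            nu_powers=tuple(d["nu_powers"]),
            include_etiv=bool(d["include_etiv"]),
            age_offset=float(d["age_offset"]),
            etiv_center=float(d["etiv_center"]),
        )


def _power_name(p: float) -> str:
    return "log_t" if p == 0.0 else f"t^{p:g}"


def _fp_terms(t: np.ndarray, powers: tuple[float, ...]) -> list[np.ndarray]:
    cols = []
    for p in powers:
        if p == 0.0:
            if np.any(t <= 0):
                raise ValueError(
                    "log power requires log(age + c) > 0, i.e. age + c > 1"
                )
            cols.append(np.log(t))
        elif p != int(p):
            if np.any(t <= 0):
                raise ValueError(
                    f"fractional power {p} requires log(age + c) > 0"
                )
            cols.append(t ** p)
        else:
            cols.append(t ** p)
    return cols


def build_design_basis(age, sex_male, etiv, spec: BasisSpec):
    """Evaluate the design matrices for (mu, sigma, nu).

    Parameters
    ----------
    age : array of ages in years (>= 0)
    sex_male : array of 0/1 male indicators
    etiv : array of eTIV in mm^3 (ignored unless ``spec.include_etiv``)
    spec : BasisSpec

    Returns a dict with keys ``"mu"``, ``"sigma"``, ``"nu"`` mapping to
    (n, p) arrays whose columns follow ``spec.*_columns``.
    """
    age = np.asarray(age, dtype=float)
    sex_male = np.asarray(sex_male, dtype=float)
    if np.any(age < 0) or np.any(age + spec.age_offset <= 0):
        raise ValueError("ages must satisfy age >= 0 and age + c > 0")
    n = age.shape[0]
    t = np.log(age + spec.age_offset)

    ones = np.ones(n)
    mu_cols = [ones] + _fp_terms(t, spec.mu_powers) + [sex_male]
    if spec.include_etiv:
        etiv = np.asarray(etiv, dtype=float)
        if np.any(etiv <= 0):
            raise ValueError("eTIV must be strictly positive")
        mu_cols.append(np.log(etiv) - spec.etiv_center)
    sigma_cols = [ones] + _fp_terms(t, spec.sigma_powers)
    nu_cols = [ones] + _fp_terms(t, spec.nu_powers)

    return {
        "mu": np.column_stack(mu_cols),
        "sigma": np.column_stack(sigma_cols),
        "nu": np.column_stack(nu_cols),
    }


def candidate_mu_power_sets(max_degree: int = 2) -> list[tuple[float, ...]]:
    """Enumerate FP power sets for the location predictor, degree <= 3.

    Ordered by degree then lexicographically, which fixes the tie-break
    order used in model selection (fewer terms first, then lexicographic).
    """
    from itertools import combinations

    out: list[tuple[float, ...]] = []
    for deg in range(1, min(max_degree, 3) + 1):
        for combo in combinations(FP_POWERS, deg):
            out.append(tuple(sorted(combo)))
    return out
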