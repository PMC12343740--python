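"""Closed-form estimation of emergence-model parameters from control arms.

Every parameter of the additive null has an exact moment inversion on
pooled counts, and for binomial data with one shared probability per
stratum the pooled-proportion inversion *is* the maximum-likelihood
estimate:

- ``m0`` from no-parasitoid ambient vials of one host:
  ``m0 = -ln(sum(flies) / (n*H0)) / T``
- ``m_tau`` from no-parasitoid heated vials (given ``m0``):
  ``m_tau = -ln(sum(flies) / (n*H0)) - m0*T`` (may be negative: heat can
  accelerate development and raise emergence)
- ``a0`` from ambient parasitoid vials of one host-parasitoid pair:
  ``a0 = -ln(mean_flies / (H0*exp(-m0*T))) / P``, clamped to 0 when mean
  fly emergence exceeds the no-parasitoid expectation
- ``epsilon`` from the same vials' wasp counts:
  ``epsilon = mean_wasps / (H0*exp(-m0*T)*(1 - exp(-a0*P)))``, clamped to
  [0, 1]

Uncertainty comes from a nonparametric bootstrap that resamples vials with
replacement independently within each fitting stratum (preserving the
design structure), refits the whole chain, and reports the standard
deviation across resamples.

The ``invert_*`` functions are the pure closed forms on real-valued pooled
means; the ``fit_*`` functions wrap them for lists of vial records and emit
``UserWarning`` for clamps and sign flips so callers can record them.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (AMBIENT, NO_PARASITOID, DesignCell, DesignConstants,
                     VialRecord)
from .errors import (ConfigurationError, DataError, DegenerateEstimateError,
                     ValidationError)
from .model import ModelParams, as_rng

#: Pair strata with fewer total wasps than this are flagged as low-count.
LOW_WASP_TOTAL = 10


# ---------------------------------------------------------------------------
# pure closed-form inversions (real-valued pooled means)
# ---------------------------------------------------------------------------

def invert_baseline_mortality(mean_flies: float, eggs_per_vial: float,
                              end_day: float) -> float:
    """``m0`` from mean control fly emergence per vial."""
    survival = mean_flies / eggs_per_vial
    if survival > 1:
        raise DataError(
            f"mean flies {mean_flies} exceeds eggs per vial {eggs_per_vial}")
    if survival <= 0:
        raise DegenerateEstimateError(
            "zero fly emergence: m0 estimate is infinite")
    return -math.log(survival) / end_day


def invert_heat_mortality(mean_flies: float, eggs_per_vial: float,
                          m0: float, end_day: float) -> float:
    """``m_tau`` from mean heated control emergence, given ``m0``."""
    survival = mean_flies / eggs_per_vial
    if survival > 1:
        raise DataError(
            f"mean flies {mean_flies} exceeds eggs per vial {eggs_per_vial}")
    if survival <= 0:
        raise DegenerateEstimateError(
            "zero fly emergence under heat: m_tau estimate is infinite")
    return -math.log(survival) - m0 * end_day


def invert_attack_rate(mean_flies: float, eggs_per_vial: float, m0: float,
                       end_day: float, wasp_count: int
                       ) -> tuple[float, bool]:
    """``a0`` from mean fly emergence with parasitoids present.

    Returns ``(a0, clamped)``; ``clamped`` is True when the estimate was
    negative (more flies than the no-parasitoid expectation) and was set
    to 0.
    """
    if wasp_count <= 0:
        raise ValidationError("wasp_count must be positive to fit a0")
    if mean_flies <= 0:
        raise DegenerateEstimateError(
            "zero fly emergence with parasitoids: a0 estimate is infinite; "
            "a joint-likelihood fit on wasp counts would be needed")
    baseline = eggs_per_vial * math.exp(-m0 * end_day)
    ratio = mean_flies / baseline
    if ratio >= 1:
        return 0.0, True
    return -math.log(ratio) / wasp_count, False


def invert_conversion(mean_wasps: float, eggs_per_vial: float, m0: float,
                      end_day: float, a0: float, wasp_count: int
                      ) -> tuple[float, bool]:
    """``epsilon`` from mean wasp emergence, given ``m0`` and ``a0``.

    Returns ``(epsilon, clamped)``.
    """
    if a0 <= 0:
        if mean_wasps > 0:
            raise DataError(
                "wasps emerged but fitted attack rate is zero: "
                "inconsistent fly and wasp data")
        return 0.0, False
    infected = (eggs_per_vial * math.exp(-m0 * end_day)
                * (1.0 - math.exp(-a0 * wasp_count)))
    eps = mean_wasps / infected
    if eps > 1:
        return 1.0, True
    if eps < 0:
        return 0.0, True
    return eps, False


# ---------------------------------------------------------------------------
# per-stratum fits on vial records
# ---------------------------------------------------------------------------

def _check_stratum(vials: Sequence[VialRecord], *, parasitoid: str | None,
                   heat_timing: str | None, what: str) -> None:
    if not vials:
        raise ValidationError(f"no vials supplied for {what}")
    hosts = {v.cell.host for v in vials}
    if len(hosts) > 1:
        raise ValidationError(f"{what}: vials mix hosts {sorted(hosts)}")
    if parasitoid is not None:
        wrong = {v.cell.parasitoid for v in vials} - {parasitoid}
        if parasitoid == NO_PARASITOID and wrong:
            raise ValidationError(f"{what}: expected no-parasitoid vials")
        if parasitoid != NO_PARASITOID:
            paras = {v.cell.parasitoid for v in vials}
            if len(paras) > 1 or NO_PARASITOID in paras:
                raise ValidationError(
                    f"{what}: vials mix parasitoid levels {sorted(paras)}")
    if heat_timing is not None:
        timings = {v.cell.heat_timing for v in vials}
        if heat_timing == AMBIENT and timings != {AMBIENT}:
            raise ValidationError(f"{what}: expected ambient vials")
        if heat_timing != AMBIENT and (len(timings) > 1 or AMBIENT in timings):
            raise ValidationError(
                f"{what}: vials mix heat timings {sorted(timings)}")


def fit_baseline_mortality(vials: Sequence[VialRecord],
                           constants: DesignConstants) -> float:
    """Fit ``m0`` from one host's no-parasitoid ambient vials."""
    _check_stratum(vials, parasitoid=NO_PARASITOID, heat_timing=AMBIENT,
                   what="fit_baseline_mortality")
    mean_flies = sum(v.flies for v in vials) / len(vials)
    return invert_baseline_mortality(mean_flies, constants.eggs_per_vial,
                                     constants.end_day)


def fit_heat_mortality(vials: Sequence[VialRecord], m0: float,
                       constants: DesignConstants) -> float:
    """Fit ``m_tau`` from one host's no-parasitoid heated vials."""
    _check_stratum(vials, parasitoid=NO_PARASITOID, heat_timing="heated",
                   what="fit_heat_mortality")
    mean_flies = sum(v.flies for v in vials) / len(vials)
    m_tau = invert_heat_mortality(mean_flies, constants.eggs_per_vial, m0,
                                  constants.end_day)
    if m_tau < 0:
        warnings.warn(
            f"m_tau = {m_tau:.4f} < 0: emergence higher under heat than "
            "ambient (survival benefit)", UserWarning, stacklevel=2)
    return m_tau


def fit_attack_rate(vials: Sequence[VialRecord], m0: float,
                    constants: DesignConstants) -> float:
    """Fit ``a0`` from one host-parasitoid pair's ambient vials."""
    _check_stratum(vials, parasitoid=vials[0].cell.parasitoid if vials else "",
                   heat_timing=AMBIENT, what="fit_attack_rate")
    mean_flies = sum(v.flies for v in vials) / len(vials)
    a0, clamped = invert_attack_rate(mean_flies, constants.eggs_per_vial,
                                     m0, constants.end_day,
                                     constants.wasp_count)
    if clamped:
        warnings.warn(
            "a0 clamped to 0: mean fly emergence exceeds the no-parasitoid "
            "expectation", UserWarning, stacklevel=2)
    return a0


def fit_conversion(vials: Sequence[VialRecord], m0: float, a0: float,
                   constants: DesignConstants) -> float:
    """Fit ``epsilon`` from the same ambient pair vials' wasp counts."""
    _check_stratum(vials, parasitoid=vials[0].cell.parasitoid if vials else "",
                   heat_timing=AMBIENT, what="fit_conversion")
    mean_wasps = sum(v.wasps for v in vials) / len(vials)
    eps, clamped = invert_conversion(mean_wasps, constants.eggs_per_vial,
                                     m0, constants.end_day, a0,
                                     constants.wasp_count)
    if clamped:
        warnings.warn(f"epsilon clamped to {eps:g}", UserWarning,
                      stacklevel=2)
    return eps


# ---------------------------------------------------------------------------
# whole-dataset fit with bootstrap uncertainty
# ---------------------------------------------------------------------------

def m0_key(host: str) -> str:
    return f"m0[{host}]"


def m_tau_key(host: str, timing: str) -> str:
    return f"m_tau[{host},{timing}]"


def a0_key(host: str, parasitoid: str) -> str:
    return f"a0[{host},{parasitoid}]"


def epsilon_key(host: str, parasitoid: str) -> str:
    return f"epsilon[{host},{parasitoid}]"


@dataclass
class FitResult:
    """Point estimates, bootstrap SEs, usage counts, and fit warnings."""

    params: ModelParams
    standard_errors: dict[str, float | None]
    n_vials_used: dict[str, int]
    warnings: list[str] = field(default_factory=list)
    n_bootstrap: int = 0
    se_method: str = "bootstrap_sd"

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "standard_errors": self.standard_errors,
            "n_vials_used": self.n_vials_used,
            "warnings": list(self.warnings),
            "n_bootstrap": self.n_bootstrap,
            "se_method": self.se_method,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "FitResult":
        return cls(
            params=ModelParams.from_dict(data["params"]),
            standard_errors=dict(data.get("standard_errors", {})),
            n_vials_used=dict(data.get("n_vials_used", {})),
            warnings=list(data.get("warnings", [])),
            n_bootstrap=int(data.get("n_bootstrap", 0)),
            se_method=str(data.get("se_method", "bootstrap_sd")),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def flat_estimates(self) -> dict[str, float]:
        """Point estimates keyed like the SE / n_vials mappings."""
        p = self.params
        out: dict[str, float] = {}
        for host, v in p.m0.items():
            out[m0_key(host)] = v
        for (host, timing), v in p.m_tau.items():
            out[m_tau_key(host, timing)] = v
        for (host, para), v in p.a0.items():
            out[a0_key(host, para)] = v
        for (host, para), v in p.epsilon.items():
            out[epsilon_key(host, para)] = v
        return out

    def to_frame(self) -> pd.DataFrame:
        """Flat table: key, estimate, se, n_vials, warning."""
        rows = []
        for key, est in self.flat_estimates().items():
            notes = "; ".join(w for w in self.warnings if w.startswith(key))
            rows.append({
                "key": key, "estimate": est,
                "se": self.standard_errors.get(key),
                "n_vials": self.n_vials_used.get(key),
                "warning": notes,
            })
        return pd.DataFrame(rows,
                            columns=["key", "estimate", "se", "n_vials",
                                     "warning"])


def _group_strata(dataset: Sequence[VialRecord]
                  ) -> dict[tuple[str, str, str], dict[str, np.ndarray]]:
    """Group counts by (host, parasitoid, heat_timing)."""
    groups: dict[tuple[str, str, str], dict[str, list[int]]] = {}
    for v in dataset:
        key = (v.cell.host, v.cell.parasitoid, v.cell.heat_timing)
        g = groups.setdefault(key, {"flies": [], "wasps": []})
        g["flies"].append(v.flies)
        g["wasps"].append(v.wasps)
    return {k: {"flies": np.asarray(g["flies"], dtype=float),
                "wasps": np.asarray(g["wasps"], dtype=float)}
            for k, g in groups.items()}


def _point_fit(means: Mapping[tuple[str, str, str], tuple[float, float]],
               hosts: Sequence[str], timings: Sequence[str],
               pairs: Sequence[tuple[str, str]],
               constants: DesignConstants,
               pool_epsilon: bool = False,
               notes: list[str] | None = None) -> ModelParams:
    """Run the full inversion chain on per-stratum (mean flies, mean wasps)."""
    h0, t_end, p_wasps = (constants.eggs_per_vial, constants.end_day,
                          constants.wasp_count)
    m0: dict[str, float] = {}
    m_tau: dict[tuple[str, str], float] = {}
    a0: dict[tuple[str, str], float] = {}
    eps: dict[tuple[str, str], float] = {}
    for host in hosts:
        m0[host] = invert_baseline_mortality(
            means[(host, NO_PARASITOID, AMBIENT)][0], h0, t_end)
        for timing in timings:
            mt = invert_heat_mortality(
                means[(host, NO_PARASITOID, timing)][0], h0, m0[host], t_end)
            m_tau[(host, timing)] = mt
            if notes is not None and mt < 0:
                notes.append(f"{m_tau_key(host, timing)}: negative "
                             "(survival benefit under heat)")
    for host, para in pairs:
        mean_f, mean_w = means[(host, para, AMBIENT)]
        a, clamped_a = invert_attack_rate(mean_f, h0, m0[host], t_end,
                                          p_wasps)
        a0[(host, para)] = a
        if notes is not None and clamped_a:
            notes.append(f"{a0_key(host, para)}: clamped to 0 (mean flies "
                         "above no-parasitoid expectation)")
        if not pool_epsilon:
            e, clamped_e = invert_conversion(mean_w, h0, m0[host], t_end, a,
                                             p_wasps)
            eps[(host, para)] = e
            if notes is not None and clamped_e:
                notes.append(f"{epsilon_key(host, para)}: clamped to {e:g}")
    if pool_epsilon:
        # single epsilon per parasitoid: pool expected-infected and wasp
        # means over hosts
        by_para: dict[str, tuple[float, float]] = {}
        for host, para in pairs:
            mean_w = means[(host, para, AMBIENT)][1]
            infected = (h0 * math.exp(-m0[host] * t_end)
                        * (1.0 - math.exp(-a0[(host, para)] * p_wasps)))
            w_sum, inf_sum = by_para.get(para, (0.0, 0.0))
            by_para[para] = (w_sum + mean_w, inf_sum + infected)
        for host, para in pairs:
            w_sum, inf_sum = by_para[para]
            if inf_sum <= 0:
                if w_sum > 0:
                    raise DataError(
                        f"wasps emerged for {para} but pooled attack rate "
                        "is zero")
                eps[(host, para)] = 0.0
            else:
                eps[(host, para)] = min(1.0, max(0.0, w_sum / inf_sum))
    return ModelParams(m0=m0, m_tau=m_tau, a0=a0, epsilon=eps)


def fit_all(dataset: Sequence[VialRecord], constants: DesignConstants,
            n_bootstrap: int = 1000,
            rng: np.random.Generator | int | None = None,
            pool_epsilon: bool = False) -> FitResult:
    """Fit every parameter from a dataset's control arms, with bootstrap SEs.

    Fitting strata: per host the ambient no-parasitoid vials (``m0``) and
    each heated no-parasitoid stratum (``m_tau``); per host-parasitoid pair
    the ambient parasitoid vials (``a0`` and ``epsilon``). Combined
    heat x parasitoid cells are never used for fitting — they are what the
    null projection is tested against.

    Bootstrap: vials are resampled with replacement within each stratum,
    the whole inversion chain is refit, and the SE is the standard
    deviation of each parameter across ``n_bootstrap`` resamples
    (``n_bootstrap=0`` skips SEs).
    """
    if not dataset:
        raise ValidationError("empty dataset")
    groups = _group_strata(dataset)
    hosts = sorted({v.cell.host for v in dataset})
    timings = sorted({v.cell.heat_timing for v in dataset
                      if v.cell.heat_timing != AMBIENT})
    pairs = sorted({(v.cell.host, v.cell.parasitoid) for v in dataset
                    if v.cell.has_parasitoid})

    required: list[tuple[str, str, str]] = []
    for host in hosts:
        required.append((host, NO_PARASITOID, AMBIENT))
        required.extend((host, NO_PARASITOID, t) for t in timings)
    required.extend((host, para, AMBIENT) for host, para in pairs)
    missing = [key for key in required if key not in groups]
    if missing:
        raise ValidationError(
            "dataset lacks required control strata: "
            + ", ".join(f"({h}, {p}, {t})" for h, p, t in missing))

    means = {key: (float(groups[key]["flies"].mean()),
                   float(groups[key]["wasps"].mean()))
             for key in required}
    notes: list[str] = []
    params = _point_fit(means, hosts, timings, pairs, constants,
                        pool_epsilon=pool_epsilon, notes=notes)

    n_used: dict[str, int] = {}
    for host in hosts:
        n_used[m0_key(host)] = len(groups[(host, NO_PARASITOID, AMBIENT)]
                                   ["flies"])
        for timing in timings:
            n_used[m_tau_key(host, timing)] = len(
                groups[(host, NO_PARASITOID, timing)]["flies"])
    for host, para in pairs:
        n = len(groups[(host, para, AMBIENT)]["flies"])
        n_used[a0_key(host, para)] = n
        n_used[epsilon_key(host, para)] = n
        total_wasps = float(groups[(host, para, AMBIENT)]["wasps"].sum())
        if total_wasps < LOW_WASP_TOTAL:
            notes.append(f"{epsilon_key(host, para)}: low wasp total "
                         f"({total_wasps:.0f} < {LOW_WASP_TOTAL}) in the "
                         "fitting stratum")

    flat_keys = list(FitResult(params, {}, {}).flat_estimates())
    ses: dict[str, float | None]
    if n_bootstrap <= 0:
        ses = {key: None for key in flat_keys}
        notes.append("bootstrap skipped (n_bootstrap=0): SEs unavailable")
    else:
        rng = as_rng(rng)
        draws: dict[str, list[float]] = {key: [] for key in flat_keys}
        failures = 0
        for _ in range(n_bootstrap):
            boot_means = {}
            for key in required:
                flies = groups[key]["flies"]
                wasps = groups[key]["wasps"]
                idx = rng.integers(0, len(flies), size=len(flies))
                boot_means[key] = (float(flies[idx].mean()),
                                   float(wasps[idx].mean()))
            try:
                boot = _point_fit(boot_means, hosts, timings, pairs,
                                  constants, pool_epsilon=pool_epsilon)
            except (DegenerateEstimateError, DataError):
                failures += 1
                continue
            flat = FitResult(boot, {}, {}).flat_estimates()
            for key, value in flat.items():
                draws[key].append(value)
        ses = {}
        for key in flat_keys:
            values = np.asarray(draws[key])
            if len(values) >= 2:
                ses[key] = float(values.std(ddof=1))
            else:
                ses[key] = None
                notes.append(f"{key}: SE unavailable "
                             f"({len(values)} usable bootstrap resamples)")
        for key, n in n_used.items():
            if n == 1 and ses.get(key) == 0.0:
                ses[key] = None
                notes.append(f"{key}: SE unavailable (single vial)")
        if failures:
            notes.append(f"bootstrap: {failures}/{n_bootstrap} resamples "
                         "failed (degenerate) and were skipped")
    return FitResult(params=params, standard_errors=ses,
                     n_vials_used=n_used, warnings=notes,
                     n_bootstrap=max(n_bootstrap, 0))
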