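"""Single-generation host-parasitoid emergence model.

The model is a Nicholson-Bailey variant reduced to one generation. A vial
starts with ``H0`` host eggs. A fraction ``exp(-m0*T - m_tau)`` of them
develops to the end of day ``T`` under baseline per-day mortality ``m0``
plus a cumulative differential mortality ``m_tau`` incurred by a 24-h heat
pulse at timing ``tau``. Surviving larvae escape infection by ``P``
searching female wasps with the classic Nicholson-Bailey escape probability
``exp(-a0*P)`` (``a0`` = attack rate per wasp) and emerge as adult flies;
the infected complement yields an adult wasp with probability ``epsilon``
per host. Expected emergence under the additive null is therefore

    F = H0 * exp(-m0*T - m_tau) * exp(-a0*P)
    W = epsilon * H0 * exp(-m0*T - m_tau) * (1 - exp(-a0*P))

so baseline, heat, and parasitism mortalities add in the exponent
(``m0*T + m_tau + a0*P``) with no interaction term.

Two instrumentation knobs deliberately break additivity for testing: a
synergy exponent ``gamma`` added to the mortality exponent, and a
multiplier ``delta`` on the attack rate, both applied only in cells where
heat and parasitoids co-occur. With ``gamma=0`` and ``delta=1`` the model
is exactly the additive null.

The stochastic realization of a vial is a single multinomial draw of size
``H0`` over the fates {fly, wasp, neither}; its expectations match the
closed forms exactly. Hosts that are infected but fail to yield a wasp are
pooled into "neither": only emerged adults are observable, so an infected
host's death is indistinguishable from background death.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import yaml

from .design import AMBIENT, DesignCell, DesignConstants, VialRecord
from .errors import ConfigurationError, ValidationError

#: Tolerance for fate-probability bookkeeping (sum-to-one, tiny negatives).
PROB_TOL = 1e-12


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce a seed or generator into a ``numpy.random.Generator``.

    A single generator is threaded explicitly through every stochastic
    operation in the package; no global random state is touched.
    """
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


class FateProbs(NamedTuple):
    """Per-egg fate probabilities for one treatment cell."""

    p_fly: float
    p_wasp: float
    p_none: float

    def validate(self) -> "FateProbs":
        total = self.p_fly + self.p_wasp + self.p_none
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"fate probabilities sum to {total}, not 1")
        for name, p in zip(self._fields, self):
            if not -PROB_TOL <= p <= 1 + PROB_TOL:
                raise ValidationError(f"{name} = {p} outside [0, 1]")
        return self


@dataclass
class ModelParams:
    """Full parameter set of the emergence model.

    Mappings are keyed by design-level labels:

    - ``m0``: host -> baseline mortality per day (>= 0)
    - ``m_tau``: (host, heat_timing) -> cumulative differential mortality;
      may be negative (heat can raise emergence); ambient defaults to 0
    - ``a0``: (host, parasitoid) -> attack rate per female wasp (>= 0)
    - ``epsilon``: (host, parasitoid) -> wasp yield per infected host, in [0, 1]
    - ``synergy_gamma``: (host, parasitoid, heat_timing) -> extra mortality
      exponent in combined heat x parasitoid cells only (default 0)
    - ``synergy_delta``: (host, parasitoid, heat_timing) -> attack-rate
      multiplier in combined cells only (default 1, must be >= 0)
    """

    m0: dict[str, float]
    m_tau: dict[tuple[str, str], float]
    a0: dict[tuple[str, str], float]
    epsilon: dict[tuple[str, str], float]
    synergy_gamma: dict[tuple[str, str, str], float] = field(default_factory=dict)
    synergy_delta: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for host, value in self.m0.items():
            if value < 0:
                raise ValidationError(f"m0[{host}] = {value} < 0")
        for key, value in self.a0.items():
            if value < 0:
                raise ValidationError(f"a0[{key}] = {value} < 0")
        for key, value in self.epsilon.items():
            if not 0 <= value <= 1:
                raise ValidationError(f"epsilon[{key}] = {value} outside [0, 1]")
        for key, value in self.synergy_delta.items():
            if value < 0:
                raise ValidationError(f"synergy_delta[{key}] = {value} < 0")

    # -- keyed lookups -----------------------------------------------------
    def baseline_mortality(self, host: str) -> float:
        try:
            return self.m0[host]
        except KeyError:
            raise ConfigurationError(f"missing parameter m0[{host}]") from None

    def heat_mortality(self, host: str, heat_timing: str) -> float:
        key = (host, heat_timing)
        if key in self.m_tau:
            return self.m_tau[key]
        if heat_timing == AMBIENT:
            return 0.0  # no heat pulse, no differential mortality
        raise ConfigurationError(
            f"missing parameter m_tau[{host}, {heat_timing}]")

    def attack_rate(self, host: str, parasitoid: str) -> float:
        try:
            return self.a0[(host, parasitoid)]
        except KeyError:
            raise ConfigurationError(
                f"missing parameter a0[{host}, {parasitoid}]") from None

    def conversion(self, host: str, parasitoid: str) -> float:
        try:
            return self.epsilon[(host, parasitoid)]
        except KeyError:
            raise ConfigurationError(
                f"missing parameter epsilon[{host}, {parasitoid}]") from None

    def gamma(self, host: str, parasitoid: str, heat_timing: str) -> float:
        return self.synergy_gamma.get((host, parasitoid, heat_timing), 0.0)

    def delta(self, host: str, parasitoid: str, heat_timing: str) -> float:
        return self.synergy_delta.get((host, parasitoid, heat_timing), 1.0)

    def is_null(self) -> bool:
        """True when no higher-order term deviates from the additive null."""
        return (all(v == 0 for v in self.synergy_gamma.values())
                and all(v == 1 for v in self.synergy_delta.values()))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def nest2(flat: Mapping[tuple[str, str], float]) -> dict:
            out: dict = {}
            for (a, b), v in flat.items():
                out.setdefault(a, {})[b] = v
            return out

        def nest3(flat: Mapping[tuple[str, str, str], float]) -> dict:
            out: dict = {}
            for (a, b, c), v in flat.items():
                out.setdefault(a, {}).setdefault(b, {})[c] = v
            return out

        return {
            "m0": dict(self.m0),
            "m_tau": nest2(self.m_tau),
            "a0": nest2(self.a0),
            "epsilon": nest2(self.epsilon),
            "synergy_gamma": nest3(self.synergy_gamma),
            "synergy_delta": nest3(self.synergy_delta),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelParams":
        def flat2(nested: Mapping) -> dict[tuple[str, str], float]:
            return {(a, b): float(v)
                    for a, inner in nested.items()
                    for b, v in inner.items()}

        def flat3(nested: Mapping) -> dict[tuple[str, str, str], float]:
            return {(a, b, c): float(v)
                    for a, inner in nested.items()
                    for b, deeper in inner.items()
                    for c, v in deeper.items()}

        return cls(
            m0={k: float(v) for k, v in data["m0"].items()},
            m_tau=flat2(data.get("m_tau", {})),
            a0=flat2(data.get("a0", {})),
            epsilon=flat2(data.get("epsilon", {})),
            synergy_gamma=flat3(data.get("synergy_gamma", {})),
            synergy_delta=flat3(data.get("synergy_delta", {})),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" \
            else yaml.safe_load(text)
        return cls.from_dict(data)


def fate_probabilities(params: ModelParams, cell: DesignCell,
                       constants: DesignConstants) -> FateProbs:
    """Per-egg probabilities of emerging as a fly, a wasp, or neither.

    With ``s = exp(-(m0*T + m_tau + gamma*1[combined]))`` and
    ``q = exp(-a0*delta*P_eff)`` (``P_eff = P`` in parasitoid cells, else 0):
    ``p_fly = s*q``, ``p_wasp = s*(1-q)*epsilon``, ``p_none`` the rest.
    """
    exponent = (params.baseline_mortality(cell.host) * constants.end_day
                + params.heat_mortality(cell.host, cell.heat_timing))
    if cell.has_parasitoid and cell.heated:
        exponent += params.gamma(cell.host, cell.parasitoid, cell.heat_timing)
    if exponent < 0:
        raise ValidationError(
            f"mortality exponent {exponent:.6g} < 0 for cell {cell}: "
            "implied survival exceeds 1 (check m_tau/gamma against m0*T)")
    survival = math.exp(-exponent)
    if cell.has_parasitoid and constants.wasp_count > 0:
        attack = params.attack_rate(cell.host, cell.parasitoid)
        if cell.heated:
            attack *= params.delta(cell.host, cell.parasitoid,
                                   cell.heat_timing)
        escape = math.exp(-attack * constants.wasp_count)
        eps = params.conversion(cell.host, cell.parasitoid)
    else:
        escape, eps = 1.0, 0.0
    p_fly = survival * escape
    p_wasp = survival * (1.0 - escape) * eps
    p_none = 1.0 - p_fly - p_wasp
    if -PROB_TOL < p_none < 0.0:  # floating underflow near certainty
        p_none = 0.0
    return FateProbs(p_fly, p_wasp, p_none).validate()


def expected_emergence(params: ModelParams, cell: DesignCell,
                       constants: DesignConstants) -> tuple[float, float]:
    """Expected adult flies ``F`` and wasps ``W`` for one treatment cell."""
    probs = fate_probabilities(params, cell, constants)
    h0 = constants.eggs_per_vial
    return h0 * probs.p_fly, h0 * probs.p_wasp


def simulate_vial(params: ModelParams, cell: DesignCell,
                  constants: DesignConstants,
                  rng: np.random.Generator | int | None,
                  replicate_id: str = "r1") -> VialRecord:
    """Draw one vial's (flies, wasps, neither) as a single multinomial."""
    rng = as_rng(rng)
    probs = fate_probabilities(params, cell, constants)
    flies, wasps, _ = rng.multinomial(constants.eggs_per_vial, probs)
    return VialRecord(cell=cell, replicate_id=replicate_id,
                      eggs=constants.eggs_per_vial,
                      flies=int(flies), wasps=int(wasps))


def simulate_experiment(params: ModelParams, cells: Sequence[DesignCell],
                        constants: DesignConstants, n_replicates: int,
                        rng: np.random.Generator | int | None
                        ) -> list[VialRecord]:
    """Simulate ``n_replicates`` vials for every cell (labels r1..rn)."""
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = as_rng(rng)
    records: list[VialRecord] = []
    for cell in cells:
        probs = fate_probabilities(params, cell, constants)
        draws = rng.multinomial(constants.eggs_per_vial, probs,
                                size=n_replicates)
        for i in range(n_replicates):
            records.append(VialRecord(
                cell=cell, replicate_id=f"r{i + 1}",
                eggs=constants.eggs_per_vial,
                flies=int(draws[i, 0]), wasps=int(draws[i, 1])))
    return records
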