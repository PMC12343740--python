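"""Synthetic factorial vial datasets with the structure of the microcosm study.

The generator emulates a fully crossed design — 3 host species x 4
parasitoid levels (including a no-parasitoid control) x 4 heat timings
(ambient, before, during, after) — with 6 replicate vials of 50 eggs per
cell: 48 cells, 288 vials, 14,400 eggs. Counts are single multinomial
draws per vial from the emergence model, so every downstream stage
(validation, fitting, null projection, rates) is testable without any
external data.

The ``default_truth`` parameter values are invented test fixtures chosen
to be realistic in magnitude and detectable without being degenerate; they
are NOT estimates for any real host-parasitoid community. Scenario presets
inject the two higher-order pathways of biological interest: extra
combined-stress mortality (``synergy_mortality``, via the gamma exponent)
and heat damage to freshly laid parasitoid eggs (``antagonism_parasitism``,
via the delta attack-rate multiplier).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .design import (AMBIENT, NO_PARASITOID, DesignConstants, VialRecord,
                     enumerate_design)
from .errors import ValidationError
from .model import ModelParams, simulate_experiment

HOSTS = ("birchii", "bipectinata", "simulans")
PARASITOIDS = ("Asobara", "Ganaspis", "Leptopilina")
TIMINGS = (AMBIENT, "before", "during", "after")
HEATED_TIMINGS = ("before", "during", "after")

PRESETS = ("additive_null", "synergy_mortality", "antagonism_parasitism")

#: Synergy exponent used by the ``synergy_mortality`` preset.
SYNERGY_GAMMA = 0.6
#: Attack-rate multiplier used by the ``antagonism_parasitism`` preset.
ANTAGONISM_DELTA = 0.05


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified simulation setting."""

    name: str
    truth: ModelParams
    constants: DesignConstants
    seed: int


def default_truth() -> ModelParams:
    """Additive-null fixture parameters for three hosts x three parasitoids.

    Baseline mortalities give 60-85% control survival over the 8-day
    window. One host ("birchii") is heat-stressed, most strongly by a late
    pulse; the other two emerge mildly *better* under heat (negative
    ``m_tau``, emulating accelerated development). Negative ``m_tau``
    magnitudes are kept below each host's ``m0*T`` so implied survival
    stays below 1. Attack rates put the infected fraction at 35-65% and
    wasp yields sit in 0.5-0.9. All synergy terms are at their null
    values.
    """
    m0 = {"birchii": 0.035, "bipectinata": 0.055, "simulans": 0.048}
    m_tau = {
        ("birchii", "before"): 0.30,
        ("birchii", "during"): 0.45,
        ("birchii", "after"): 1.10,
        ("bipectinata", "before"): -0.18,
        ("bipectinata", "during"): -0.22,
        ("bipectinata", "after"): -0.18,
        ("simulans", "before"): -0.20,
        ("simulans", "during"): -0.25,
        ("simulans", "after"): -0.20,
    }
    a0 = {
        ("birchii", "Asobara"): 0.32,
        ("birchii", "Ganaspis"): 0.22,
        ("birchii", "Leptopilina"): 0.26,
        ("bipectinata", "Asobara"): 0.16,
        ("bipectinata", "Ganaspis"): 0.20,
        ("bipectinata", "Leptopilina"): 0.15,
        ("simulans", "Asobara"): 0.21,
        ("simulans", "Ganaspis"): 0.30,
        ("simulans", "Leptopilina"): 0.18,
    }
    epsilon = {
        ("birchii", "Asobara"): 0.80,
        ("birchii", "Ganaspis"): 0.65,
        ("birchii", "Leptopilina"): 0.70,
        ("bipectinata", "Asobara"): 0.55,
        ("bipectinata", "Ganaspis"): 0.60,
        ("bipectinata", "Leptopilina"): 0.50,
        ("simulans", "Asobara"): 0.75,
        ("simulans", "Ganaspis"): 0.85,
        ("simulans", "Leptopilina"): 0.60,
    }
    return ModelParams(m0=m0, m_tau=m_tau, a0=a0, epsilon=epsilon)


def scenario_preset(name: str, seed: int = 0) -> Scenario:
    """Resolve a named preset to a fully specified :class:`Scenario`.

    - ``additive_null``: the default truth, no higher-order terms.
    - ``synergy_mortality``: extra mortality (gamma > 0) when heat hits
      during the foraging window in parasitoid cells.
    - ``antagonism_parasitism``: attack success nearly abolished
      (delta << 1) when heat falls during or after the foraging window.
    """
    if name not in PRESETS:
        raise ValidationError(
            f"unknown scenario {name!r}; presets: {', '.join(PRESETS)}")
    truth = default_truth()
    if name == "synergy_mortality":
        truth = replace(truth, synergy_gamma={
            (h, p, "during"): SYNERGY_GAMMA
            for h in HOSTS for p in PARASITOIDS})
    elif name == "antagonism_parasitism":
        truth = replace(truth, synergy_delta={
            (h, p, t): ANTAGONISM_DELTA
            for h in HOSTS for p in PARASITOIDS
            for t in ("during", "after")})
    return Scenario(name=name, truth=truth, constants=DesignConstants(),
                    seed=seed)


def generate(scenario: Scenario) -> list[VialRecord]:
    """Simulate the full factorial dataset for a scenario.

    Deterministic given ``scenario.seed``; with the default constants the
    result is 48 cells x 6 replicates = 288 vials (14,400 eggs).
    """
    cells = enumerate_design(scenario.constants, HOSTS,
                             (NO_PARASITOID,) + PARASITOIDS, TIMINGS)
    return simulate_experiment(scenario.truth, cells, scenario.constants,
                               scenario.constants.replicates_per_cell,
                               scenario.seed)
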