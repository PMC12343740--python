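"""Null projection and confidence-interval overlap test for additivity.

The question: do heat exposure and parasitism act on emergence through
independently multiplying survival factors (additive exponents), or are
there higher-order effects (synergy/antagonism)? The test projects each
combined heat x parasitoid cell under the additive null using parameters
fitted *only* from control arms, then compares 95% intervals:

- simulated interval: percentile (2.5/97.5) of the per-pseudo-experiment
  mean emergence over ``n_sims`` simulated experiments of
  ``replicates_per_cell`` vials each;
- observed interval: percentile bootstrap of the replicate mean.

A cell is flagged ``higher_order`` exactly when the two intervals are
disjoint; touching endpoints count as overlap (conservative toward the
null). No p-values or multiplicity correction are attached — the decision
rule is binary overlap, and interval-overlap screening is conservative
relative to a nominal 5% test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import AMBIENT, DesignCell, DesignConstants, VialRecord
from .errors import ValidationError
from .fitting import FitResult
from .model import fate_probabilities, as_rng

logger = logging.getLogger(__name__)

ADDITIVE = "additive"
HIGHER_ORDER = "higher_order"


@dataclass(frozen=True)
class IntervalSummary:
    """A mean with a 95% interval and the method that produced it."""

    mean: float
    lower95: float
    upper95: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not self.lower95 <= self.mean <= self.upper95:
            raise ValidationError(
                f"interval [{self.lower95}, {self.upper95}] does not "
                f"bracket mean {self.mean}")


@dataclass(frozen=True)
class AdditivityVerdict:
    """Observed vs null-projected intervals for one combined cell."""

    cell: DesignCell
    observed_flies: IntervalSummary
    observed_wasps: IntervalSummary
    simulated_flies: IntervalSummary
    simulated_wasps: IntervalSummary
    verdict_flies: str
    verdict_wasps: str


def overlap_verdict(observed: IntervalSummary,
                    simulated: IntervalSummary) -> str:
    """``higher_order`` iff the two 95% intervals are disjoint.

    Boundary touching counts as overlap, i.e. ``additive``: the rule only
    rejects the null when the intervals share no point at all.
    """
    disjoint = (observed.upper95 < simulated.lower95
                or simulated.upper95 < observed.lower95)
    return HIGHER_ORDER if disjoint else ADDITIVE


def observed_interval(vials: Sequence[VialRecord],
                      n_boot: int = 10_000,
                      rng: np.random.Generator | int | None = None
                      ) -> tuple[IntervalSummary, IntervalSummary]:
    """Percentile-bootstrap 95% interval of the replicate mean (flies, wasps).

    Vials are resampled jointly, so the fly and wasp intervals come from
    the same resampled replicate sets. A single replicate yields a
    degenerate point interval (with a logged warning).
    """
    if not vials:
        raise ValidationError("observed_interval: empty vial list")
    flies = np.asarray([v.flies for v in vials], dtype=float)
    wasps = np.asarray([v.wasps for v in vials], dtype=float)
    n = len(vials)
    if n == 1:
        logger.warning("observed_interval: single replicate for cell %s; "
                       "degenerate point interval", vials[0].cell)
        return (IntervalSummary(flies[0], flies[0], flies[0], 1,
                                "single-replicate point"),
                IntervalSummary(wasps[0], wasps[0], wasps[0], 1,
                                "single-replicate point"))
    rng = as_rng(rng)
    idx = rng.integers(0, n, size=(n_boot, n))
    fly_means = flies[idx].mean(axis=1)
    wasp_means = wasps[idx].mean(axis=1)
    method = f"bootstrap-percentile(n_boot={n_boot})"
    out = []
    for means, observed_mean in ((fly_means, flies.mean()),
                                 (wasp_means, wasps.mean())):
        lo, hi = np.percentile(means, [2.5, 97.5])
        mean = float(observed_mean)
        out.append(IntervalSummary(mean, min(float(lo), mean),
                                   max(float(hi), mean), n, method))
    return out[0], out[1]


def project_null(fit: FitResult, cell: DesignCell,
                 constants: DesignConstants, n_sims: int = 10_000,
                 rng: np.random.Generator | int | None = None
                 ) -> tuple[IntervalSummary, IntervalSummary]:
    """Simulate the additive null for one cell; 95% interval of the mean.

    Each of the ``n_sims`` pseudo-experiments draws
    ``constants.replicates_per_cell`` multinomial vials from the fitted
    fate probabilities (synergy terms held at their null values) and
    records the mean flies and wasps across replicates.
    """
    if n_sims < 100:
        raise ValidationError("project_null: n_sims must be >= 100")
    rng = as_rng(rng)
    probs = fate_probabilities(fit.params, cell, constants)
    n_reps = constants.replicates_per_cell
    draws = rng.multinomial(constants.eggs_per_vial, probs,
                            size=(n_sims, n_reps))
    fly_means = draws[:, :, 0].mean(axis=1)
    wasp_means = draws[:, :, 1].mean(axis=1)
    method = f"simulated-null-percentile(n_sims={n_sims},n_reps={n_reps})"
    out = []
    for means in (fly_means, wasp_means):
        lo, hi = np.percentile(means, [2.5, 97.5])
        mean = float(means.mean())
        out.append(IntervalSummary(mean, min(float(lo), mean),
                                   max(float(hi), mean), n_sims, method))
    return out[0], out[1]


def run_additivity_suite(dataset: Sequence[VialRecord], fit: FitResult,
                         constants: DesignConstants, n_sims: int = 10_000,
                         rng: np.random.Generator | int | None = None,
                         n_boot: int = 10_000) -> list[AdditivityVerdict]:
    """Overlap verdicts for every combined heat x parasitoid cell.

    Cells are processed in sorted (host, parasitoid, timing) order so a
    seeded run is reproducible. Returns an empty list (with a warning) if
    the dataset has no combined cells.
    """
    rng = as_rng(rng)
    by_cell: dict[DesignCell, list[VialRecord]] = {}
    for v in dataset:
        if v.cell.has_parasitoid and v.cell.heated:
            by_cell.setdefault(v.cell, []).append(v)
    if not by_cell:
        logger.warning("run_additivity_suite: no combined "
                       "heat x parasitoid cells in dataset")
        return []
    verdicts = []
    for cell in sorted(by_cell):
        obs_f, obs_w = observed_interval(by_cell[cell], n_boot=n_boot,
                                         rng=rng)
        sim_f, sim_w = project_null(fit, cell, constants, n_sims=n_sims,
                                    rng=rng)
        verdicts.append(AdditivityVerdict(
            cell=cell,
            observed_flies=obs_f, observed_wasps=obs_w,
            simulated_flies=sim_f, simulated_wasps=sim_w,
            verdict_flies=overlap_verdict(obs_f, sim_f),
            verdict_wasps=overlap_verdict(obs_w, sim_w)))
    return verdicts


def verdicts_to_frame(verdicts: Iterable[AdditivityVerdict]) -> pd.DataFrame:
    """Long-format verdict table, one row per cell x channel."""
    rows = []
    for v in verdicts:
        for channel, obs, sim, verdict in (
                ("flies", v.observed_flies, v.simulated_flies,
                 v.verdict_flies),
                ("wasps", v.observed_wasps, v.simulated_wasps,
                 v.verdict_wasps)):
            rows.append({
                "host": v.cell.host, "parasitoid": v.cell.parasitoid,
                "timing": v.cell.heat_timing, "channel": channel,
                "obs_mean": obs.mean, "obs_lo": obs.lower95,
                "obs_hi": obs.upper95,
                "sim_mean": sim.mean, "sim_lo": sim.lower95,
                "sim_hi": sim.upper95, "verdict": verdict})
    return pd.DataFrame(rows, columns=[
        "host", "parasitoid", "timing", "channel", "obs_mean", "obs_lo",
        "obs_hi", "sim_mean", "sim_lo", "sim_hi", "verdict"])


def plot_verdicts(verdicts: Sequence[AdditivityVerdict], path: str,
                  channel: str = "flies") -> None:
    """Observed-vs-simulated interval chart, one column per combined cell.

    Stars mark cells whose intervals are disjoint (higher-order effects).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if channel not in ("flies", "wasps"):
        raise ValidationError(f"unknown channel {channel!r}")
    fig, ax = plt.subplots(figsize=(max(6.0, 0.5 * len(verdicts) + 2), 4.5))
    for i, v in enumerate(sorted(verdicts, key=lambda x: x.cell)):
        obs = v.observed_flies if channel == "flies" else v.observed_wasps
        sim = v.simulated_flies if channel == "flies" else v.simulated_wasps
        verdict = v.verdict_flies if channel == "flies" else v.verdict_wasps
        ax.errorbar([i - 0.15], [obs.mean],
                    yerr=[[obs.mean - obs.lower95], [obs.upper95 - obs.mean]],
                    fmt="o", color="tab:blue",
                    label="observed" if i == 0 else None)
        ax.errorbar([i + 0.15], [sim.mean],
                    yerr=[[sim.mean - sim.lower95], [sim.upper95 - sim.mean]],
                    fmt="s", color="tab:orange",
                    label="simulated null" if i == 0 else None)
        if verdict == HIGHER_ORDER:
            top = max(obs.upper95, sim.upper95)
            ax.annotate("*", (i, top), ha="center", fontsize=14)
    cells = sorted(v.cell for v in verdicts)
    ax.set_xticks(range(len(cells)))
    ax.set_xticklabels(
        [f"{c.host}\n{c.parasitoid}\n{c.heat_timing}" for c in cells],
        fontsize=7)
    ax.set_ylabel(f"emerged {channel} (mean per vial, 95% CI)")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
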