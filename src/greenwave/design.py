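"""Factorial experimental design: richness plots crossed with consumer-removal subplots.

The design mirrors a split-plot grassland experiment: whole plots carry a
planted species-richness level, and each plot is divided into subplots that
each receive exactly one consumer-removal treatment (pesticide regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field

RICHNESS_LEVELS = (1, 4, 16)
TREATMENTS = (
    "control",
    "insecticide",
    "foliar_fungicide",
    "soil_fungicide",
    "all_pesticides",
)

#: plot counts per planted richness level in the reference field design
DEFAULT_RICHNESS_COUNTS = {1: 15, 4: 9, 16: 9}


def subplot_id(plot_id: str, treatment: str) -> str:
    """Deterministic subplot identifier: ``<plot_id>-<treatment>``."""
    return f"{plot_id}-{treatment}"


@dataclass(frozen=True)
class Plot:
    plot_id: str
    richness: int


@dataclass(frozen=True)
class Subplot:
    subplot_id: str
    plot_id: str
    richness: int
    treatment: str


@dataclass
class Design:
    """Enumerated plots, subplots and study years of a factorial experiment."""

    plots: list[Plot]
    subplots: list[Subplot]
    treatments: tuple[str, ...]
    years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_plots, n_treat = len(self.plots), len(self.treatments)
        if len(self.subplots) != n_plots * n_treat:
            raise ValueError(
                f"subplot count {len(self.subplots)} != plots x treatments "
                f"({n_plots} x {n_treat})"
            )
        per_plot: dict[str, set[str]] = {}
        for sp in self.subplots:
            per_plot.setdefault(sp.plot_id, set()).add(sp.treatment)
        for pid, treats in per_plot.items():
            if treats != set(self.treatments):
                raise ValueError(f"plot {pid} does not carry one subplot per treatment")

    @property
    def richness_levels(self) -> tuple[int, ...]:
        return tuple(sorted({p.richness for p in self.plots}))

    @property
    def n_combinations(self) -> int:
        """Distinct (richness, treatment) cells."""
        return len({(sp.richness, sp.treatment) for sp in self.subplots})

    def subplot_meta(self) -> dict[str, Subplot]:
        return {sp.subplot_id: sp for sp in self.subplots}


def build_design(
    richness_counts: dict[int, int],
    treatments: tuple[str, ...] | list[str] = TREATMENTS,
    years: list[int] | None = None,
) -> Design:
    """Enumerate a factorial design from plot counts per richness level.

    Plot identifiers are ``p<serial>r<richness>``, assigned in ascending
    richness order, so identical inputs always yield identical identifier
    sequences.

    Parameters
    ----------
    richness_counts
        Mapping of planted richness level to number of whole plots.
    treatments
        Consumer-removal treatment labels; one subplot per plot per label.
    years
        Calendar years of the study (optional; used by simulation).
    """
    treatments = tuple(treatments)
    seen: set[str] = set()
    for t in treatments:
        if t in seen:
            raise ValueError(f"duplicate treatment label: {t!r}")
        seen.add(t)
    for level, count in richness_counts.items():
        if count <= 0:
            raise ValueError(f"plot count for richness {level} must be positive")

    plots: list[Plot] = []
    serial = 0
    for level in sorted(richness_counts):
        for _ in range(richness_counts[level]):
            serial += 1
            plots.append(Plot(plot_id=f"p{serial:02d}r{level}", richness=level))

    subplots = [
        Subplot(
            subplot_id=subplot_id(p.plot_id, t),
            plot_id=p.plot_id,
            richness=p.richness,
            treatment=t,
        )
        for p in plots
        for t in treatments
    ]
    return Design(plots=plots, subplots=subplots, treatments=treatments,
                  years=list(years or []))
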