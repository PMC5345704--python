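"""Piecewise population-size histories.

A demographic model is an ordered list of epochs, each either constant in
size or growing/shrinking exponentially, expressed in generations before
present.  Sizes are stored as numbers of chromosomes (2N) because that is
how the human models in the literature are usually quoted.  The solver only
ever sees the *relative* size ``rho(t) = 2N(t) / 2N0`` where ``N0`` is the
reference diploid size of the model.

Presets cover the fitted West-African and Out-of-Africa (OOA) human
histories used throughout the package: an approximate doubling of the
ancestral size before the OOA split, the OOA bottleneck to 13% of the
expanded size 2000 generations ago, a second bottleneck to 55% with slow
recovery (0.31%/generation) 920 generations ago, and recent rapid growth
from 205 generations ago (1.66%/generation African, 1.95%/generation OOA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Epoch",
    "DemographicModel",
    "preset_african",
    "preset_ooa",
    "preset_bottleneck",
    "preset_bottleneck_growth",
    "preset_constant",
]

# Expanded (pre-OOA-bottleneck) size in chromosomes; the reference size for
# split-era comparisons.
TWO_N_EXPANDED = 29_240.0
# Ancestral size before the pre-split doubling (exact doubling assumed).
TWO_N_ANCESTRAL = TWO_N_EXPANDED / 2.0

# Event times in generations before present.
T_DOUBLING = 5_920.0       # event a: pre-split expansion
T_OOA_BOTTLENECK = 2_000.0 # event b: OOA bottleneck (13%)
T_SECOND_BOTTLENECK = 920.0  # event c: 55% bottleneck + 0.31%/gen recovery
T_RECENT_GROWTH = 205.0    # event d: rapid growth in both populations

OOA_BOTTLENECK_FRACTION = 0.13
SECOND_BOTTLENECK_FRACTION = 0.55
RECOVERY_RATE = 0.0031
GROWTH_RATE_OOA = 0.0195
GROWTH_RATE_AFRICAN = 0.0166

# Default start of the oldest (ancestral, constant) epoch.  The solve only
# needs the ancestral population to sit at equilibrium, which the initial
# condition provides, so this just has to predate event a.
T_ANCESTRAL_START = 10_000.0


class DemographyError(ValueError):
    """Invalid demographic model or query outside its span."""


@dataclass(frozen=True)
class Epoch:
    """One piece of a size history, in generations before present.

    ``start_gen`` is the older boundary, ``end_gen`` the younger one
    (``start_gen > end_gen >= 0``).  ``size2N_at_start`` is the number of
    chromosomes at the older boundary; for an exponential epoch the size at
    ``t`` generations before present is
    ``size2N_at_start * exp(growth_rate * (start_gen - t))``.
    """

    start_gen: float
    end_gen: float
    kind: str  # "constant" | "exponential"
    size2N_at_start: float
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "exponential"):
            raise DemographyError(f"unknown epoch kind {self.kind!r}")
        if not self.start_gen > self.end_gen >= 0:
            raise DemographyError(
                f"epoch must satisfy start_gen > end_gen >= 0, got "
                f"({self.start_gen}, {self.end_gen})"
            )
        if not self.size2N_at_start > 0:
            raise DemographyError("size2N_at_start must be positive")
        if self.kind == "constant" and self.growth_rate != 0.0:
            raise DemographyError("constant epoch must have growth_rate 0")
        if self.kind == "exponential" and self.growth_rate == 0.0:
            raise DemographyError("exponential epoch must have nonzero rate")

    def size2N_at(self, t_gen: float) -> float:
        if not (self.end_gen <= t_gen <= self.start_gen):
            raise DemographyError(
                f"t_gen={t_gen} outside epoch [{self.end_gen}, {self.start_gen}]"
            )
        if self.kind == "constant":
            return self.size2N_at_start
        return self.size2N_at_start * math.exp(
            self.growth_rate * (self.start_gen - t_gen)
        )

    def size2N_at_end(self) -> float:
        return self.size2N_at(self.end_gen)


@dataclass(frozen=True)
class DemographicModel:
    """Contiguous epochs, oldest first, plus the reference diploid size N0.

    Epochs must tile [oldest start, 0] with no gaps.  Sizes may jump at
    epoch boundaries (instantaneous bottlenecks); at a boundary instant the
    *younger* epoch's size applies.
    """

    name: str
    epochs: tuple[Epoch, ...]
    N0: float  # reference diploid size; rho(t) = size2N(t) / (2 * N0)

    def __post_init__(self) -> None:
        if not self.epochs:
            raise DemographyError("model needs at least one epoch")
        if not self.N0 > 0:
            raise DemographyError("N0 must be positive")
        for older, younger in zip(self.epochs, self.epochs[1:]):
            if older.end_gen != younger.start_gen:
                raise DemographyError(
                    f"epochs not contiguous at {older.end_gen} != "
                    f"{younger.start_gen}"
                )
        if self.epochs[-1].end_gen != 0:
            raise DemographyError("youngest epoch must end at the present (0)")

    @property
    def start_gen(self) -> float:
        """Older boundary of the model span, generations before present."""
        return self.epochs[0].start_gen

    def epoch_at(self, t_gen: float) -> Epoch:
        """Epoch governing time ``t_gen``; younger epoch wins at boundaries."""
        if not (0 <= t_gen <= self.start_gen):
            raise DemographyError(
                f"t_gen={t_gen} outside model span [0, {self.start_gen}]"
            )
        # Walk youngest to oldest so a boundary instant resolves to the
        # younger epoch (left-continuity in forward time).
        for ep in reversed(self.epochs):
            if ep.end_gen <= t_gen <= ep.start_gen:
                return ep
        raise DemographyError(f"no epoch covers t_gen={t_gen}")  # pragma: no cover

    def size2N_at(self, t_gen: float) -> float:
        return self.epoch_at(t_gen).size2N_at(t_gen)

    def rho_at(self, t_gen: float) -> float:
        """Relative size rho(t) = 2N(t) / 2N0."""
        return self.size2N_at(t_gen) / (2.0 * self.N0)

    def boundaries(self) -> list[float]:
        """All epoch boundary times, oldest first, including endpoints."""
        times = [self.epochs[0].start_gen]
        times.extend(ep.end_gen for ep in self.epochs)
        return times

    def to_coalescent_time(self, t_gen: float) -> float:
        """Convert generations to units of 2N0 generations."""
        return t_gen / (2.0 * self.N0)

    def from_coalescent_time(self, tau: float) -> float:
        return tau * 2.0 * self.N0

    def to_config(self) -> dict:
        """Plain-dict form for structured-text (YAML) round-tripping."""
        return {
            "name": self.name,
            "N0": self.N0,
            "epochs": [
                {
                    "start_gen": ep.start_gen,
                    "end_gen": ep.end_gen,
                    "kind": ep.kind,
                    "size2N_at_start": ep.size2N_at_start,
                    "growth_rate": ep.growth_rate,
                }
                for ep in self.epochs
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "DemographicModel":
        return cls(
            name=cfg["name"],
            epochs=tuple(Epoch(**ep) for ep in cfg["epochs"]),
            N0=float(cfg["N0"]),
        )


def preset_african(
    ancestral_start_gen: float = T_ANCESTRAL_START,
    doubling_gen: float = T_DOUBLING,
) -> DemographicModel:
    """West-African history: ancestral doubling, then constant until recent
    exponential growth (1.66%/generation) starting 205 generations ago.

    N0 references the expanded (post-doubling, pre-OOA-bottleneck) size
    2N = 29,240 so that both population models share a time and theta scale.
    """
    epochs = (
        Epoch(ancestral_start_gen, doubling_gen, "constant", TWO_N_ANCESTRAL),
        Epoch(doubling_gen, T_RECENT_GROWTH, "constant", TWO_N_EXPANDED),
        Epoch(
            T_RECENT_GROWTH, 0.0, "exponential", TWO_N_EXPANDED,
            GROWTH_RATE_AFRICAN,
        ),
    )
    return DemographicModel("african", epochs, N0=TWO_N_EXPANDED / 2.0)


def preset_ooa(
    ancestral_start_gen: float = T_ANCESTRAL_START,
    doubling_gen: float = T_DOUBLING,
) -> DemographicModel:
    """Out-of-Africa history: shared ancestral doubling, 13% bottleneck at
    2000 generations ago, 55% second bottleneck with 0.31%/generation
    recovery at 920, and 1.95%/generation growth from 205 generations ago.
    """
    two_n_bottleneck = OOA_BOTTLENECK_FRACTION * TWO_N_EXPANDED  # 3801.2
    two_n_second = SECOND_BOTTLENECK_FRACTION * two_n_bottleneck
    two_n_at_growth = two_n_second * math.exp(
        RECOVERY_RATE * (T_SECOND_BOTTLENECK - T_RECENT_GROWTH)
    )
    epochs = (
        Epoch(ancestral_start_gen, doubling_gen, "constant", TWO_N_ANCESTRAL),
        Epoch(doubling_gen, T_OOA_BOTTLENECK, "constant", TWO_N_EXPANDED),
        Epoch(T_OOA_BOTTLENECK, T_SECOND_BOTTLENECK, "constant", two_n_bottleneck),
        Epoch(
            T_SECOND_BOTTLENECK, T_RECENT_GROWTH, "exponential", two_n_second,
            RECOVERY_RATE,
        ),
        Epoch(T_RECENT_GROWTH, 0.0, "exponential", two_n_at_growth,
              GROWTH_RATE_OOA),
    )
    return DemographicModel("ooa", epochs, N0=TWO_N_EXPANDED / 2.0)


def preset_constant(two_N: float, span_gen: float, name: str = "constant"
                    ) -> DemographicModel:
    """Single constant-size epoch spanning ``span_gen`` generations."""
    return DemographicModel(
        name, (Epoch(span_gen, 0.0, "constant", two_N),), N0=two_N / 2.0
    )


def preset_bottleneck(
    rho: float,
    t_start: float,
    two_N0: float = TWO_N_EXPANDED,
    pre_duration_gen: float | None = None,
) -> DemographicModel:
    """Instantaneous size reduction to fraction ``rho`` at ``t_start``
    generations before present, held to the present.

    The pre-bottleneck epoch (size 2N0) lasts ``pre_duration_gen``
    generations (default: equal to ``t_start``); solves typically start at
    the bottleneck itself from an equilibrium initial condition.
    """
    if not 0 < rho <= 1:
        raise DemographyError("rho must be in (0, 1]")
    if pre_duration_gen is None:
        pre_duration_gen = t_start
    if rho == 1.0:
        return preset_constant(two_N0, t_start + pre_duration_gen,
                               name="bottleneck")
    epochs = (
        Epoch(t_start + pre_duration_gen, t_start, "constant", two_N0),
        Epoch(t_start, 0.0, "constant", rho * two_N0),
    )
    return DemographicModel("bottleneck", epochs, N0=two_N0 / 2.0)


def preset_bottleneck_growth(
    rho: float,
    rate: float,
    t_start: float,
    two_N0: float = TWO_N_EXPANDED,
    pre_duration_gen: float | None = None,
) -> DemographicModel:
    """Instantaneous reduction to fraction ``rho`` at ``t_start`` followed
    immediately by exponential growth at ``rate`` per generation."""
    if not 0 < rho <= 1:
        raise DemographyError("rho must be in (0, 1]")
    if pre_duration_gen is None:
        pre_duration_gen = t_start
    epochs = (
        Epoch(t_start + pre_duration_gen, t_start, "constant", two_N0),
        Epoch(t_start, 0.0, "exponential", rho * two_N0, rate),
    )
    return DemographicModel("bottleneck_growth", epochs, N0=two_N0 / 2.0)
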