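"""Genome and demography specifications for the forward breed simulation.

The simulated system is a set of pig breeds descending from a common
ancestral Fisher-Wright population.  A :class:`DemographyPlan` describes,
per lineage, a contiguous sequence of epochs (generation intervals with a
constant diploid effective size Ne) plus split events at which a parent
lineage gives rise to two child lineages that evolve independently
afterwards.  A :class:`GenomeSpec` describes the neutral genome: a number
of chromosomes with a genetic length in Morgans and an expected number of
new mutations per chromosome per transmitted gamete (infinite-sites).

Population-genetic rescaling ("desk scale") divides every Ne and every
epoch duration by a factor ``lam`` and multiplies the mutation rate by
``lam``, preserving drift intensities t/(2Ne) and the population-scaled
diversity 4*Ne*mu up to integer rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class InvalidScalingError(ValueError):
    """Raised when a rescaling factor collapses an epoch or an Ne."""


class InvalidPlanError(ValueError):
    """Raised when a demography plan is internally inconsistent."""


@dataclass(frozen=True)
class GenomeSpec:
    """Neutral genome layout.

    Parameters
    ----------
    n_chromosomes:
        Number of autosomes (default 10).
    chrom_length:
        Genetic length of each chromosome in Morgans (default 1.0).
    mutations_per_chrom_per_meiosis:
        Expected number of new (infinite-sites) mutations appearing on a
        transmitted gamete, per chromosome (default 2.0).
    """

    n_chromosomes: int = 10
    chrom_length: float = 1.0
    mutations_per_chrom_per_meiosis: float = 2.0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if not self.chrom_length > 0:
            raise ValueError("chrom_length must be > 0")
        if self.mutations_per_chrom_per_meiosis < 0:
            raise ValueError("mutation rate must be >= 0")

    def rescaled(self, lam: float) -> "GenomeSpec":
        """Return a spec with the mutation rate multiplied by ``lam``."""
        if not lam > 0:
            raise InvalidScalingError("scaling factor must be > 0")
        return replace(
            self,
            mutations_per_chrom_per_meiosis=self.mutations_per_chrom_per_meiosis * lam,
        )


@dataclass(frozen=True)
class Epoch:
    """Half-open generation interval [start, end) with constant diploid Ne."""

    start: int
    end: int
    ne: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidPlanError(f"epoch [{self.start},{self.end}) is empty")
        if self.ne < 2:
            raise InvalidPlanError(f"Ne must be >= 2, got {self.ne}")


@dataclass(frozen=True)
class Split:
    """At ``generation``, ``parent`` gives rise to two independent children."""

    generation: int
    parent: str
    children: tuple[str, str]


@dataclass(frozen=True)
class DemographyPlan:
    """Per-lineage epoch schedules plus split events.

    ``epochs`` maps a lineage label to its ordered, contiguous epochs.  The
    root lineage starts at generation 0; each child lineage starts at its
    split generation.  Every lineage must be covered by epochs from its
    origin to either a split in which it is the parent or the final
    generation of the plan.
    """

    epochs: dict[str, tuple[Epoch, ...]]
    splits: tuple[Split, ...] = ()
    scaling_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.scaling_factor > 0:
            raise InvalidPlanError("scaling_factor must be > 0")
        self._validate()

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> str:
        children = {c for s in self.splits for c in s.children}
        roots = [name for name in self.epochs if name not in children]
        if len(roots) != 1:
            raise InvalidPlanError(f"expected exactly one root lineage, got {roots}")
        return roots[0]

    @property
    def final_generation(self) -> int:
        return max(e.end for eps in self.epochs.values() for e in eps)

    @property
    def terminal_lineages(self) -> tuple[str, ...]:
        parents = {s.parent for s in self.splits}
        return tuple(name for name in self.epochs if name not in parents)

    def origin(self, lineage: str) -> int:
        for s in self.splits:
            if lineage in s.children:
                return s.generation
        return 0

    def split_of(self, parent: str) -> Split | None:
        for s in self.splits:
            if s.parent == parent:
                return s
        return None

    def ne_at(self, lineage: str, generation: int) -> int:
        for e in self.epochs[lineage]:
            if e.start <= generation < e.end:
                return e.ne
        raise InvalidPlanError(
            f"generation {generation} not covered for lineage {lineage!r}"
        )

    def _validate(self) -> None:
        self.root  # uniqueness check
        final = self.final_generation
        for name, eps in self.epochs.items():
            start = self.origin(name)
            if eps[0].start != start:
                raise InvalidPlanError(
                    f"lineage {name!r} epochs start at {eps[0].start}, "
                    f"expected origin {start}"
                )
            for a, b in zip(eps, eps[1:]):
                if a.end != b.start:
                    raise InvalidPlanError(
                        f"lineage {name!r} epochs not contiguous at {a.end}"
                    )
            split = self.split_of(name)
            end = split.generation if split is not None else final
            if eps[-1].end != end:
                raise InvalidPlanError(
                    f"lineage {name!r} epochs end at {eps[-1].end}, expected {end}"
                )
        for s in self.splits:
            if s.parent not in self.epochs:
                raise InvalidPlanError(f"unknown split parent {s.parent!r}")
            for c in s.children:
                if c not in self.epochs:
                    raise InvalidPlanError(f"unknown split child {c!r}")


def rescale_plan(plan: DemographyPlan, lam: float) -> DemographyPlan:
    """Divide every Ne and epoch duration by ``lam`` (rounded to integers).

    Generation boundaries are mapped as ``round(g / lam)`` so that shared
    boundaries (splits, epoch edges) stay consistent across lineages.  Drift
    intensities t/(2*Ne) are preserved up to rounding.  The companion
    mutation-rate scaling lives in :meth:`GenomeSpec.rescaled`.

    Raises
    ------
    InvalidScalingError
        If any epoch collapses to zero generations or any Ne falls below 2.
    """
    if not lam > 0:
        raise InvalidScalingError("scaling factor must be > 0")
    if lam == 1.0:
        return plan

    def g(x: int) -> int:
        return int(round(x / lam))

    new_epochs: dict[str, tuple[Epoch, ...]] = {}
    for name, eps in plan.epochs.items():
        out = []
        for e in eps:
            start, end = g(e.start), g(e.end)
            ne = int(round(e.ne / lam))
            if end <= start:
                raise InvalidScalingError(
                    f"epoch [{e.start},{e.end}) of {name!r} collapses at lam={lam}"
                )
            if ne < 2:
                raise InvalidScalingError(
                    f"Ne {e.ne} of {name!r} falls below 2 at lam={lam}"
                )
            out.append(Epoch(start, end, ne))
        new_epochs[name] = tuple(out)
    new_splits = tuple(
        Split(g(s.generation), s.parent, s.children) for s in plan.splits
    )
    return DemographyPlan(
        epochs=new_epochs, splits=new_splits, scaling_factor=plan.scaling_factor * lam
    )


def pig_demography_plan() -> DemographyPlan:
    """Phylogenetic history of the three simulated pig breeds (full scale).

    A common ancestral population (Ne 3500) evolves for 6400 generations and
    then splits into an Asian and a European lineage.  The Asian lineage
    runs at Ne 800 until generation 9915, Ne 600 until 9975 and Ne 300 until
    generation 10000, ending as breed AS.  The European lineage runs at Ne
    800 until 9915 and Ne 600 until 9960, where it splits into breeds EU1
    and EU2, each at Ne 400 until 9975 and Ne 150 until generation 10000.
    """
    return DemographyPlan(
        epochs={
            "ANC": (Epoch(0, 6400, 3500),),
            "EUR": (Epoch(6400, 9915, 800), Epoch(9915, 9960, 600)),
            "AS": (
                Epoch(6400, 9915, 800),
                Epoch(9915, 9975, 600),
                Epoch(9975, 10000, 300),
            ),
            "EU1": (Epoch(9960, 9975, 400), Epoch(9975, 10000, 150)),
            "EU2": (Epoch(9960, 9975, 400), Epoch(9975, 10000, 150)),
        },
        splits=(
            Split(6400, "ANC", ("EUR", "AS")),
            Split(9960, "EUR", ("EU1", "EU2")),
        ),
    )
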