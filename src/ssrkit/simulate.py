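"""Synthetic SSR genotype tables with controlled group structure.

Allele sizes live on a di-nucleotide-like ladder (base size + 2 * repeat
count), so a miscall shifting one repeat unit moves a size by +/- 2 rather
than jumping to an arbitrary value.  Each group carries its own allele
frequency profile at informative markers; noise markers share one profile
across groups.  Redundancy pairs force one marker to mirror another's
genotypes (through a fixed size offset), which is what the redundancy
Z-score filter is meant to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import AlleleSet, GenotypeTable

__all__ = ["SynthSpec", "generate", "paper_like_presets"]


@dataclass
class SynthSpec:
    """Blueprint for one synthetic genotyping experiment.

    ``samples_per_group`` counts distinct individuals; each individual is
    observed ``replicates`` times with independent miscall/missing noise on
    the same underlying genotype.  ``informative_markers`` lists marker
    indices whose allele profiles differ between groups (``None`` = all).
    ``redundancy_pairs`` are (source, copy) marker index pairs; the copy
    mirrors the source genotype through a size offset.
    """

    n_groups: int
    samples_per_group: int | Sequence[int]
    n_markers: int
    informative_markers: Sequence[int] | None = None
    alleles_per_marker: tuple[int, int] = (4, 8)
    ploidy: int = 2
    miscall_rate: float = 0.0
    missing_rate: float = 0.0
    redundancy_pairs: Sequence[tuple[int, int]] = ()
    replicates: int = 1
    profile_concentration: float = 0.35
    seed: int = 0

    def group_sizes(self) -> list[int]:
        if isinstance(self.samples_per_group, int):
            return [self.samples_per_group] * self.n_groups
        sizes = list(self.samples_per_group)
        if len(sizes) != self.n_groups:
            raise ValueError("samples_per_group list must match n_groups")
        return sizes

    def validate(self) -> None:
        if self.n_groups < 1 or self.n_markers < 1:
            raise ValueError("need at least one group and one marker")
        if not 1 <= self.ploidy <= 4:
            raise ValueError("ploidy must be in 1..4")
        for rate in (self.miscall_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.alleles_per_marker
        if lo < 1 or hi < lo:
            raise ValueError("invalid alleles_per_marker range")
        if lo < self.ploidy:
            raise ValueError(
                f"profiles with {lo} distinct alleles cannot support ploidy "
                f"{self.ploidy}"
            )
        if self.informative_markers is not None:
            bad = [i for i in self.informative_markers if not 0 <= i < self.n_markers]
            if bad:
                raise ValueError(f"informative marker indices out of range: {bad}")
        seen: set[int] = set()
        for src, dst in self.redundancy_pairs:
            if not (0 <= src < self.n_markers and 0 <= dst < self.n_markers):
                raise ValueError("redundancy pair index out of range")
            if src == dst or src in seen or dst in seen:
                raise ValueError("redundancy pairs must be disjoint")
            if src > dst:
                raise ValueError("redundancy pair must list the source marker first")
            seen.update((src, dst))
        if any(s < 1 for s in self.group_sizes()):
            raise ValueError("each group needs at least one individual")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _marker_pools(spec: SynthSpec, rng: np.random.Generator) -> list[np.ndarray]:
    lo, hi = spec.alleles_per_marker
    pools = []
    for _ in range(spec.n_markers):
        n_alleles = int(rng.integers(lo, hi + 1))
        base = int(rng.integers(60, 160)) * 2
        repeats = rng.choice(60, size=n_alleles, replace=False)
        pools.append(np.sort(base + 2 * repeats.astype(int)))
    return pools


def _profiles(
    spec: SynthSpec, pools: list[np.ndarray], rng: np.random.Generator
) -> list[np.ndarray]:
    """Per-marker (n_groups x n_alleles) frequency profiles."""
    informative = (
        set(range(spec.n_markers))
        if spec.informative_markers is None
        else set(spec.informative_markers)
    )
    profiles = []
    for k, pool in enumerate(pools):
        conc = np.full(len(pool), spec.profile_concentration)
        if k in informative:
            prof = rng.dirichlet(conc, size=spec.n_groups)
        else:
            prof = np.tile(rng.dirichlet(np.ones(len(pool))), (spec.n_groups, 1))
        profiles.append(prof)
    return profiles


def generate(spec: SynthSpec) -> GenotypeTable:
    """Draw a labelled genotype table fully determined by ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pools = _marker_pools(spec, rng)
    profiles = _profiles(spec, pools, rng)

    copy_of = {dst: src for src, dst in spec.redundancy_pairs}
    # the copy marker mirrors its source's pool through a fixed size offset
    offsets: dict[int, int] = {}
    for dst, src in copy_of.items():
        offsets[dst] = int(pools[src].max()) + 1000 * (dst + 1)
        pools[dst] = pools[src] + offsets[dst]
        profiles[dst] = profiles[src]

    marker_ids = [f"SSR{k + 1}" for k in range(spec.n_markers)]
    sample_ids: list[str] = []
    labels: list[str] = []
    rows: list[list[AlleleSet]] = []

    for g, size in enumerate(spec.group_sizes()):
        group = f"G{g + 1}"
        for ind in range(size):
            # latent individual genotype, shared by its replicates
            base_calls: list[set[int]] = []
            for k in range(spec.n_markers):
                if k in copy_of:
                    src_alleles = base_calls[copy_of[k]]
                    base_calls.append({a + offsets[k] for a in src_alleles})
                    continue
                draw = rng.choice(
                    pools[k], size=spec.ploidy, replace=True, p=profiles[k][g]
                )
                base_calls.append(set(int(a) for a in draw))
            for rep in range(spec.replicates):
                sample_ids.append(f"{group}_I{ind + 1}_R{rep + 1}")
                labels.append(group)
                row: list[AlleleSet] = []
                for k in range(spec.n_markers):
                    alleles = set(base_calls[k])
                    if spec.miscall_rate > 0:
                        noisy = set()
                        for a in alleles:
                            if rng.random() < spec.miscall_rate:
                                a += int(rng.choice([-2, 2]))
                            noisy.add(max(a, 2))
                        alleles = noisy
                    if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                        row.append(AlleleSet())
                    else:
                        row.append(AlleleSet(frozenset(alleles)))
                rows.append(row)

    return GenotypeTable(
        sample_ids=sample_ids,
        marker_ids=marker_ids,
        cells=np.array(rows, dtype=object),
        labels=labels,
    )


def _split_sizes(total: int, groups: int) -> list[int]:
    base, extra = divmod(total, groups)
    return [base + (1 if i < extra else 0) for i in range(groups)]


def paper_like_presets(seed: int = 0) -> dict[str, SynthSpec]:
    """Four presets mirroring the shapes of the published case studies:

    - ``tobType``: 91 samples, 186 markers, 3 classes, no replicates
    - ``landRace``: 250 samples (10 groups x 5 plants x 5 replicates), 19 markers
    - ``geoVar``: 93 samples, 48 markers, 12 classes
    - ``ORvar``: 88 samples, 48 markers, 8 classes
    """
    return {
        "tobType": SynthSpec(
            n_groups=3,
            samples_per_group=_split_sizes(91, 3),
            n_markers=186,
            miscall_rate=0.02,
            seed=seed,
        ),
        "landRace": SynthSpec(
            n_groups=10,
            samples_per_group=5,
            replicates=5,
            n_markers=19,
            miscall_rate=0.02,
            seed=seed + 1,
        ),
        "geoVar": SynthSpec(
            n_groups=12,
            samples_per_group=_split_sizes(93, 12),
            n_markers=48,
            miscall_rate=0.03,
            missing_rate=0.02,
            seed=seed + 2,
        ),
        "ORvar": SynthSpec(
            n_groups=8,
            samples_per_group=11,
            n_markers=48,
            miscall_rate=0.03,
            seed=seed + 3,
        ),
    }
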