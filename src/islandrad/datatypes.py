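"""Core domain containers shared by every stage of the pipeline.

Time is measured in Ma before present everywhere: 0 at the present, growing
into the past.  Trees are rooted, binary and ultrametric; ranges are
non-empty subsets of an ordered area list; genotypes are alternate-allele
counts of diploid biallelic loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ULTRAMETRIC_TOL = 1e-6  # Ma; dating software emits tiny rounding jitter
MISSING = -1  # sentinel for missing genotypes


class ValidationError(ValueError):
    """Raised when an input fails a domain invariant."""


class TimeTree:
    """Rooted binary ultrametric phylogeny with node ages in Ma.

    Nodes are integer-indexed: tips ``0..n_tips-1`` (sorted order of their
    labels), internal nodes after that, in postorder, the root last.

    Attributes
    ----------
    n_tips : int
    age : ndarray, age of each node in Ma before present (tips = 0)
    parent : ndarray, parent index per node (-1 at the root)
    children : dict mapping internal node index -> (left, right)
    labels : list of tip labels (index-aligned with tip nodes)
    """

    def __init__(self, parent, age, children, labels, validate=True):
        self.parent = np.asarray(parent, dtype=int)
        self.age = np.asarray(age, dtype=float)
        self.children = dict(children)
        self.labels = list(labels)
        self.n_tips = len(self.labels)
        self.root = int(np.flatnonzero(self.parent < 0)[0])
        if validate:
            self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.age.size

    @property
    def crown_age(self) -> float:
        return float(self.age[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Edge length above each non-root node (root entry is 0)."""
        bl = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        bl[mask] = self.age[self.parent[mask]] - self.age[mask]
        return bl

    def postorder_internal(self):
        """Internal node indices, children always before parents."""
        order = sorted(self.children, key=lambda i: self.age[i])
        # ages strictly increase root-ward on ultrametric trees, so sorting
        # by age is a valid postorder for internal nodes; ties are broken
        # arbitrarily but never violate the child-before-parent property
        # because a parent is strictly older than its children.
        return order

    def internal_ages(self, include_root=True) -> np.ndarray:
        idx = [i for i in self.children if include_root or i != self.root]
        return self.age[np.array(sorted(idx), dtype=int)]

    def tip_index(self, label: str) -> int:
        return self.labels.index(label)

    # -- validation ---------------------------------------------------------

    def validate(self, tol: float = ULTRAMETRIC_TOL) -> None:
        if len(set(self.labels)) != self.n_tips:
            raise ValidationError("duplicate tip labels")
        for i, (a, b) in self.children.items():
            if a == b:
                raise ValidationError(f"node {i} has identical children")
            for c in (a, b):
                if self.parent[c] != i:
                    raise ValidationError("inconsistent parent/child maps")
        bl = self.branch_lengths()
        nonroot = np.arange(self.n_nodes) != self.root
        if np.any(bl[nonroot] <= 0):
            raise ValidationError("non-positive branch length")
        tips = self.age[: self.n_tips]
        if np.any(np.abs(tips) > tol):
            spread = float(np.ptp(tips))
            raise ValidationError(
                f"tree is not ultrametric: tip depth spread {spread:.3g} Ma "
                f"exceeds tolerance {tol:g} Ma"
            )

    def __repr__(self):  # pragma: no cover
        return f"TimeTree(n_tips={self.n_tips}, crown_age={self.crown_age:.4g} Ma)"


@dataclass
class ClimateSeries:
    """(age, value) paleoclimate series on the Ma-before-present axis.

    ``kind`` is either ``"d18O"`` (per-mil benthic oxygen isotopes) or
    ``"temperature"`` (deg C).  ``window`` records the smoothing applied
    ("raw" if none); ``provenance`` accumulates processing metadata.
    """

    age: np.ndarray
    value: np.ndarray
    kind: str = "temperature"
    window: str = "raw"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.age = np.asarray(self.age, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.age.size == 0:
            raise ValidationError("empty climate series")
        if self.age.size != self.value.size:
            raise ValidationError("age/value length mismatch")
        if np.any(~np.isfinite(self.age)) or np.any(~np.isfinite(self.value)):
            raise ValidationError("non-finite climate entries")
        if np.any(np.diff(self.age) <= 0):
            raise ValidationError("climate ages must be strictly increasing")
        if self.kind not in ("d18O", "temperature"):
            raise ValidationError(f"unknown climate kind {self.kind!r}")

    def __len__(self):
        return self.age.size

    def interpolator(self):
        """Linear interpolant T(age); constant extension outside the span.

        The constant extension only matters for quadrature grids that
        overshoot the series span by roundoff; analysis code checks spans
        explicitly before calling.
        """
        a, v = self.age, self.value

        def f(t):
            return np.interp(t, a, v)

        return f


@dataclass
class GeographyModel:
    """Ordered area set with pairwise distances and emergence ages.

    ``emergence_age[i]`` is the age (Ma) at which area i first became
    subaerially available; ``inf`` means available throughout.  ``strata``
    is derived: an ordered old->young list of (start_age, end_age,
    available_mask) tuples partitioning [0, ceiling].
    """

    areas: list
    distance_km: np.ndarray
    emergence_age: np.ndarray
    ceiling: float = np.inf  # oldest age the strata must cover (crown age)

    def __post_init__(self):
        self.areas = list(self.areas)
        self.distance_km = np.asarray(self.distance_km, dtype=float)
        self.emergence_age = np.asarray(self.emergence_age, dtype=float)
        k = len(self.areas)
        if self.distance_km.shape != (k, k):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.distance_km, self.distance_km.T):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.diag(self.distance_km) != 0):
            raise ValidationError("distance diagonal must be zero")
        off = self.distance_km[~np.eye(k, dtype=bool)]
        if np.any(off <= 0):
            raise ValidationError("off-diagonal distances must be positive")
        if self.emergence_age.size != k:
            raise ValidationError("one emergence age per area required")

    def available_mask(self, age: float) -> np.ndarray:
        """Boolean mask of areas subaerial at `age` Ma before present."""
        return self.emergence_age > age

    def strata(self, ceiling: float) -> list:
        """Old->young (start_age, end_age, mask) partition of [0, ceiling].

        start_age > end_age (time runs toward the present).  Boundaries are
        the finite emergence ages inside (0, ceiling).
        """
        if ceiling <= 0:
            raise ValidationError("stratum ceiling must be positive")
        cuts = sorted(
            {float(a) for a in self.emergence_age if 0.0 < a < ceiling},
            reverse=True,
        )
        bounds = [float(ceiling)] + cuts + [0.0]
        out = []
        for start, end in zip(bounds[:-1], bounds[1:]):
            mid = 0.5 * (start + end)
            mask = self.available_mask(mid)
            if not mask.any():
                raise ValidationError(
                    f"no area available in stratum ({start}, {end}) Ma"
                )
            out.append((start, end, mask))
        return out

    def dist_ref(self) -> float:
        """Geometric mean off-diagonal distance (normalises the +X kernel)."""
        k = len(self.areas)
        off = self.distance_km[~np.eye(k, dtype=bool)]
        return float(np.exp(np.mean(np.log(off))))


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci, entries = alternate-allele counts.

    ``genotype`` holds values in {0, 1, 2} with -1 for missing; diploid only.
    """

    ids: list
    pops: list
    loci: list
    genotype: np.ndarray

    def __post_init__(self):
        self.ids = list(self.ids)
        self.pops = list(self.pops)
        self.loci = list(self.loci)
        self.genotype = np.asarray(self.genotype, dtype=np.int8)
        n, m = len(self.ids), len(self.loci)
        if self.genotype.shape != (n, m):
            raise ValidationError("genotype matrix shape mismatch")
        if len(self.pops) != n:
            raise ValidationError("one population label per individual required")
        bad = ~np.isin(self.genotype, [MISSING, 0, 1, 2])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid genotype code {int(self.genotype[i, j])} at "
                f"individual {self.ids[i]!r}, locus {self.loci[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list:
        seen = {}
        for p in self.pops:
            seen.setdefault(p, None)
        return list(seen)

    def pop_mask(self, pop) -> np.ndarray:
        return np.array([p == pop for p in self.pops])

    def drop_loci(self, names) -> "GenotypeMatrix":
        """Remove loci by ID (e.g. an outlier/HWE exclusion list)."""
        drop = set(names)
        keep = [j for j, l in enumerate(self.loci) if l not in drop]
        return GenotypeMatrix(self.ids, self.pops,
                              [self.loci[j] for j in keep],
                              self.genotype[:, keep])

    def subset_pops(self, pops) -> "GenotypeMatrix":
        keep = np.array([p in set(pops) for p in self.pops])
        return GenotypeMatrix(
            [i for i, k in zip(self.ids, keep) if k],
            [p for p, k in zip(self.pops, keep) if k],
            self.loci,
            self.genotype[keep],
        )
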