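"""Categorical land-cover rasters and the class registry.

The study system is a Mediterranean landscape described by a categorical
raster. Five of the classes are Mediterranean vegetation formations ordered
along a successional gradient (herbaceous -> sparse shrubland -> dense
shrubland -> sparse woodland -> dense woodland); the remainder are other
natural covers (planted forest, riparian strips, cliffs, ...) and
non-natural covers (agriculture, built-up land). Scenario simulation,
habitat mapping and portfolio accounting all key off the registry flags
``is_natural`` and ``is_vegetation_formation``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LandCoverClass",
    "ClassRegistry",
    "LandCoverGrid",
    "default_registry",
]


@dataclass(frozen=True)
class LandCoverClass:
    """One land-cover class.

    Parameters
    ----------
    code : int
        Raster value for this class.
    name : str
        Human-readable label, e.g. ``"sparse_shrubland"``.
    is_natural : bool
        True for natural covers (candidate reserve land); False for
        built-up and agricultural classes.
    is_vegetation_formation : bool
        True for the five successional Mediterranean formations.
    successional_rank : int or None
        1 (herbaceous) .. 5 (dense woodland) for formations, None otherwise.
    """

    code: int
    name: str
    is_natural: bool
    is_vegetation_formation: bool = False
    successional_rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.is_vegetation_formation:
            if self.successional_rank is None or not 1 <= self.successional_rank <= 5:
                raise ValueError(
                    f"formation class {self.name!r} needs successional_rank in 1..5"
                )
            if not self.is_natural:
                raise ValueError(f"formation class {self.name!r} must be natural")
        elif self.successional_rank is not None:
            raise ValueError(f"non-formation class {self.name!r} cannot have a rank")


class ClassRegistry:
    """Mapping code -> :class:`LandCoverClass` with study-design invariants.

    Exactly five classes must be vegetation formations carrying the
    successional ranks 1..5 (each rank once).
    """

    def __init__(self, classes: list[LandCoverClass]):
        codes = [c.code for c in classes]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate class codes in registry")
        ranks = sorted(
            c.successional_rank for c in classes if c.is_vegetation_formation
        )
        if ranks != [1, 2, 3, 4, 5]:
            raise ValueError(
                "registry must contain exactly 5 vegetation formations "
                f"with successional ranks 1..5 (got ranks {ranks})"
            )
        self._by_code = {c.code: c for c in classes}
        self._by_name = {c.name: c for c in classes}

    def __getitem__(self, code: int) -> LandCoverClass:
        return self._by_code[code]

    def __contains__(self, code: int) -> bool:
        return code in self._by_code

    def __iter__(self):
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClassRegistry):
            return NotImplemented
        return self._by_code == other._by_code

    @property
    def codes(self) -> np.ndarray:
        return np.array(sorted(self._by_code), dtype=np.int64)

    def code_of(self, name: str) -> int:
        return self._by_name[name].code

    @property
    def natural_codes(self) -> np.ndarray:
        return np.array(
            sorted(c.code for c in self if c.is_natural), dtype=np.int64
        )

    @property
    def formation_codes(self) -> np.ndarray:
        """Formation codes ordered by successional rank 1..5."""
        forms = sorted(
            (c for c in self if c.is_vegetation_formation),
            key=lambda c: c.successional_rank,
        )
        return np.array([c.code for c in forms], dtype=np.int64)

    def formation_by_rank(self, rank: int) -> LandCoverClass:
        for c in self:
            if c.is_vegetation_formation and c.successional_rank == rank:
                return c
        raise KeyError(rank)

    def to_records(self) -> list[dict]:
        return [
            {
                "code": c.code,
                "name": c.name,
                "is_natural": c.is_natural,
                "is_vegetation_formation": c.is_vegetation_formation,
                "successional_rank": c.successional_rank,
            }
            for c in sorted(self, key=lambda c: c.code)
        ]

    @classmethod
    def from_records(cls, records: list[dict]) -> "ClassRegistry":
        return cls(
            [
                LandCoverClass(
                    code=int(r["code"]),
                    name=str(r["name"]),
                    is_natural=bool(r["is_natural"]),
                    is_vegetation_formation=bool(r["is_vegetation_formation"]),
                    successional_rank=(
                        None
                        if r.get("successional_rank") in (None, "", "None")
                        else int(r["successional_rank"])
                    ),
                )
                for r in records
            ]
        )


def default_registry() -> ClassRegistry:
    """Thirteen-class registry emulating a Mediterranean study region.

    Codes 1..5 are the successional formations; 11-13 are the non-natural
    agricultural/built classes.
    """
    return ClassRegistry(
        [
            LandCoverClass(1, "herbaceous", True, True, 1),
            LandCoverClass(2, "sparse_shrubland", True, True, 2),
            LandCoverClass(3, "dense_shrubland", True, True, 3),
            LandCoverClass(4, "sparse_woodland", True, True, 4),
            LandCoverClass(5, "dense_woodland", True, True, 5),
            LandCoverClass(6, "planted_forest", True),
            LandCoverClass(7, "riparian", True),
            LandCoverClass(8, "cliffs", True),
            LandCoverClass(9, "bare_ground", True),
            LandCoverClass(10, "water", True),
            LandCoverClass(11, "cropland", False),
            LandCoverClass(12, "plantation", False),
            LandCoverClass(13, "built", False),
        ]
    )


@dataclass
class LandCoverGrid:
    """Categorical land-cover raster plus cell geometry.

    ``classes`` is an int raster (rows x cols); ``cell_size`` is the cell
    side length in km, so each cell covers ``cell_size ** 2`` km^2.
    """

    classes: np.ndarray
    cell_size: float
    registry: ClassRegistry = field(default_factory=default_registry)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int64)
        if self.classes.ndim != 2:
            raise ValueError("classes raster must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        present = np.unique(self.classes)
        unknown = [int(c) for c in present if c not in self.registry]
        if unknown:
            raise ValueError(f"raster contains codes not in registry: {unknown}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape  # type: ignore[return-value]

    @property
    def cell_area(self) -> float:
        """Area of one cell in km^2."""
        return self.cell_size**2

    @property
    def total_area(self) -> float:
        return self.classes.size * self.cell_area

    def class_mask(self, codes) -> np.ndarray:
        return np.isin(self.classes, np.asarray(codes, dtype=np.int64))

    def natural_mask(self) -> np.ndarray:
        return self.class_mask(self.registry.natural_codes)

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.classes, return_counts=True)
        return {int(c): int(n) for c, n in zip(codes, counts)}

    def class_proportions(self) -> dict[int, float]:
        n = self.classes.size
        return {c: k / n for c, k in self.class_counts().items()}

    def copy(self) -> "LandCoverGrid":
        return LandCoverGrid(self.classes.copy(), self.cell_size, self.registry)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandCoverGrid):
            return NotImplemented
        return (
            self.cell_size == other.cell_size
            and self.registry == other.registry
            and np.array_equal(self.classes, other.classes)
        )
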