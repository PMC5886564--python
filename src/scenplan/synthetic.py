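"""Synthetic landscapes, species pools, protected areas and planning-unit grids.

No public spatial data exist for the original study system, so every
downstream stage (scenario simulation, habitat mapping, reserve selection,
portfolio evaluation) is exercised on generated inputs that reproduce the
*statistical structure* the analysis assumes:

* a categorical land-cover raster with 13 classes, five of them
  successional Mediterranean vegetation formations, spatially clumped;
* coarse-resolution species breeding ranges that are constant over
  atlas-cell blocks, with per-class habitat associations at three levels
  (strong / moderate / weak-none), restricted to natural classes;
* a clumped protected-area mask;
* a planning-unit (PU) tiling of the raster with exact shared-boundary
  adjacency.

All generators are deterministic given their seed.

Clumping is produced by rank-ordered thresholding of a Gaussian-smoothed
white-noise field: cells are sorted by the smoothed field value and class
labels are assigned along that ordering in blocks sized to the requested
proportions. Realized class proportions therefore match the request up to
integer rounding, and patches inherit the smoothing scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, ConfigurationError
from .landcover import ClassRegistry, LandCoverGrid, default_registry

__all__ = [
    "LandscapeConfig",
    "SpeciesHabitatModel",
    "ProtectedAreaMask",
    "PUGrid",
    "generate_landscape",
    "generate_species",
    "generate_protected_areas",
    "make_pu_grid",
    "DEFAULT_CLASS_MIX",
]

AssociationLevel = Literal["strong", "moderate", "weak_none"]

#: Default class mix (fractions of landscape area by class *name*).
#: A landscape dominated by agriculture and built-up land (~57%) with a
#: relatively small share of Mediterranean vegetation formations (~30%),
#: as in intensively developed Mediterranean regions where the formations
#: are the scarce, contested habitat.
DEFAULT_CLASS_MIX: dict[str, float] = {
    "herbaceous": 0.08,
    "sparse_shrubland": 0.07,
    "dense_shrubland": 0.06,
    "sparse_woodland": 0.05,
    "dense_woodland": 0.04,
    "planted_forest": 0.04,
    "riparian": 0.02,
    "cliffs": 0.01,
    "bare_ground": 0.04,
    "water": 0.02,
    "cropland": 0.28,
    "plantation": 0.09,
    "built": 0.20,
}


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape generator.

    ``class_mix`` maps class names (or codes) to area proportions that must
    sum to 1. ``autocorrelation_scale`` is the Gaussian smoothing sigma in
    cells and controls patch size.
    """

    rows: int = 64
    cols: int = 64
    cell_size: float = 1.0  # km per cell side
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    autocorrelation_scale: float = 3.0
    registry: ClassRegistry = field(default_factory=default_registry)

    def resolved_mix(self) -> dict[int, float]:
        """Class mix keyed by code, validated."""
        mix = {}
        for key, p in self.class_mix.items():
            code = key if isinstance(key, int) else self.registry.code_of(key)
            if code not in self.registry:
                raise ConfigurationError(f"unknown class {key!r} in class_mix")
            mix[int(code)] = float(p)
        if any(p < 0 for p in mix.values()):
            raise ConfigurationError("class_mix proportions must be non-negative")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_mix proportions must sum to 1 (got {sum(mix.values())})"
            )
        return mix


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    return noise


def _counts_from_proportions(props: list[float], n: int) -> list[int]:
    """Integer cell counts by largest-remainder apportionment."""
    raw = [p * n for p in props]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    remainders = np.argsort([c - r for r, c in zip(raw, counts)])  # most-negative first
    for i in range(short):
        counts[remainders[i]] += 1
    return counts


def generate_landscape(config: LandscapeConfig, seed: int) -> LandCoverGrid:
    """Generate a clumped categorical land-cover raster.

    Cells are ranked by a smoothed Gaussian noise field and class labels are
    laid out along the ranking in contiguous quantile blocks, so realized
    proportions equal the requested mix up to integer rounding (well inside
    the +-3 percentage-point contract at 64x64). The order of the quantile
    blocks is drawn at random per seed: which classes end up spatially
    adjacent varies between landscapes, so built-up land can neighbour
    vegetation formations directly (as it does around real settlements)
    rather than always being buffered by agricultural bands.
    """
    if config.rows < 8 or config.cols < 8:
        raise ConfigurationError("landscape must be at least 8x8 cells")
    if config.cell_size <= 0:
        raise ConfigurationError("cell_size must be positive")
    mix = config.resolved_mix()
    rng = np.random.default_rng(seed)
    fld = _smooth_field((config.rows, config.cols), config.autocorrelation_scale, rng)
    order = np.argsort(fld, axis=None, kind="stable")
    codes = list(rng.permutation(sorted(mix)))
    counts = _counts_from_proportions([mix[c] for c in codes], fld.size)
    flat = np.empty(fld.size, dtype=np.int64)
    start = 0
    for code, k in zip(codes, counts):
        flat[order[start : start + k]] = code
        start += k
    return LandCoverGrid(flat.reshape(config.rows, config.cols), config.cell_size, config.registry)


# ---------------------------------------------------------------------------
# species


@dataclass
class SpeciesHabitatModel:
    """One species: coarse breeding range plus land-cover associations.

    ``range_mask`` is block-constant over atlas-cell blocks resampled to the
    grid resolution. ``associations`` maps class code -> level; absent codes
    are implicitly ``weak_none``. Strong/moderate associations are restricted
    to natural classes.
    """

    species_id: str
    range_mask: np.ndarray
    associations: dict[int, AssociationLevel]
    atlas_block: int = 1

    def __post_init__(self) -> None:
        self.range_mask = np.asarray(self.range_mask, dtype=bool)

    def level(self, code: int) -> AssociationLevel:
        return self.associations.get(int(code), "weak_none")

    def suitable_codes(self) -> np.ndarray:
        return np.array(
            sorted(c for c, lv in self.associations.items() if lv in ("strong", "moderate")),
            dtype=np.int64,
        )

    def validate(self, registry: ClassRegistry) -> None:
        levels = set(self.associations.values())
        if not levels & {"strong", "moderate"}:
            raise ValueError(f"{self.species_id}: no strong/moderate association")
        for code, lv in self.associations.items():
            if lv in ("strong", "moderate") and not registry[code].is_natural:
                raise ValueError(
                    f"{self.species_id}: non-natural class {code} at level {lv}"
                )
        # block-constancy check
        b = self.atlas_block
        r, c = self.range_mask.shape
        for i0 in range(0, r, b):
            for j0 in range(0, c, b):
                blk = self.range_mask[i0 : i0 + b, j0 : j0 + b]
                if blk.any() != blk.all():
                    raise ValueError(f"{self.species_id}: range not block-constant")


def _grow_block_range(
    n_blocks: int, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Contiguous-ish random region of blocks grown from a random seed block."""
    nbr, nbc = shape
    chosen = np.zeros((nbr, nbc), dtype=bool)
    start = (int(rng.integers(nbr)), int(rng.integers(nbc)))
    frontier = [start]
    while frontier and chosen.sum() < n_blocks:
        k = int(rng.integers(len(frontier)))
        i, j = frontier.pop(k)
        if chosen[i, j]:
            continue
        chosen[i, j] = True
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < nbr and 0 <= nj < nbc and not chosen[ni, nj]:
                frontier.append((ni, nj))
    return chosen


def _habitat_area(
    sp: SpeciesHabitatModel, landscape: LandCoverGrid
) -> float:
    suitable = np.isin(landscape.classes, sp.suitable_codes()) & sp.range_mask
    return float(suitable.sum()) * landscape.cell_area


def generate_species(
    n_species: int,
    landscape: LandCoverGrid,
    atlas_block: int = 8,
    seed: int = 0,
    max_retries: int = 10,
) -> list[SpeciesHabitatModel]:
    """Generate a species pool spanning narrow-range and widespread species.

    Range sizes are stratified across species with a right-skewed
    distribution (block fractions ``0.1 + 0.9 * q**0.5`` over stratified
    quantiles q, plus jitter): regional breeding-bird pools are dominated
    by widespread species whose coarse atlas ranges span most of the
    region, with a tail of range-restricted rarities. Associations form a
    contiguous block of successional ranks (open-habitat, shrubland and
    woodland guilds: e.g. strong on sparse+dense shrubland, moderate on
    the adjacent stages), so succession between a species' own suitable
    stages does not destroy its habitat. Association breadth grows with
    range size (narrow species get a single strongly associated formation;
    widespread species up to 3 strong + 2 moderate formations). The pool must represent every branch of the
    representation-target rule that the landscape's formation area makes
    reachable (< 100 km^2 always; 100-1,000 km^2 and > 1,000 km^2 only on
    landscapes with that much formation cover); if a draw misses a reachable
    branch the generator retries with sub-seed ``seed + 10007 * attempt``,
    up to ``max_retries`` times, then raises.
    """
    if n_species < 1:
        raise ConfigurationError("n_species must be >= 1")
    reg = landscape.registry
    formations = list(reg.formation_codes)
    formation_area = float(np.isin(landscape.classes, formations).sum()) * landscape.cell_area
    # branches of the target rule reachable on this landscape
    required: list[tuple[float, float]] = [(0.0, 100.0)]
    if formation_area > 100.0 and n_species >= 2:
        required.append((100.0, 1000.0))
    if formation_area > 1000.0 and n_species >= 3:
        required.append((1000.0, np.inf))

    rows, cols = landscape.shape
    nbr = -(-rows // atlas_block)
    nbc = -(-cols // atlas_block)
    n_blocks_total = nbr * nbc

    for attempt in range(max_retries + 1):
        rng = np.random.default_rng(seed + 10007 * attempt)
        fractions = np.clip(
            0.1
            + 0.9 * np.linspace(0.0, 1.0, n_species) ** 0.5
            + rng.normal(0, 0.05, n_species),
            0.1,
            1.0,
        )
        rng.shuffle(fractions)
        species: list[SpeciesHabitatModel] = []
        for i in range(n_species):
            frac = float(fractions[i])
            n_blocks = max(1, int(round(frac * n_blocks_total)))
            blocks = _grow_block_range(n_blocks, (nbr, nbc), rng)
            mask = np.kron(blocks, np.ones((atlas_block, atlas_block), dtype=bool))
            mask = mask[:rows, :cols]
            # association breadth scales with range size; strong block is a
            # contiguous run of successional ranks, moderate extends it
            n_strong = 1 + int(round(2 * (frac - 0.1) / 0.9))
            n_strong = min(3, max(1, n_strong + int(rng.integers(-1, 2))))
            n_mod = int(rng.integers(0, 3)) if frac > 0.4 else int(rng.integers(0, 2))
            start = int(rng.integers(0, 5 - n_strong + 1))
            assoc: dict[int, AssociationLevel] = {}
            for k in range(start, start + n_strong):
                assoc[int(formations[k])] = "strong"
            below = list(range(start - 1, -1, -1))
            above = list(range(start + n_strong, 5))
            flanks = [r for pair in zip(below, above) for r in pair]
            flanks += below[len(above):] + above[len(below):]
            for k in flanks[:n_mod]:
                assoc[int(formations[k])] = "moderate"
            sp = SpeciesHabitatModel(
                species_id=f"sp{i + 1:03d}",
                range_mask=mask,
                associations=assoc,
                atlas_block=atlas_block,
            )
            sp.validate(reg)
            species.append(sp)
        areas = [_habitat_area(sp, landscape) for sp in species]
        if all(any(lo < a <= hi if hi < np.inf else a > lo for a in areas) for lo, hi in required):
            return species
    raise ConfigurationError(
        f"could not generate a species pool spanning target-rule branches "
        f"{required} in {max_retries + 1} attempts (seed {seed})"
    )


# ---------------------------------------------------------------------------
# protected areas


@dataclass
class ProtectedAreaMask:
    """Boolean raster of statutorily protected cells, aligned to the land cover."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


def generate_protected_areas(
    landscape: LandCoverGrid,
    target_fraction: float,
    seed: int,
    formation_bias: float = 0.75,
) -> ProtectedAreaMask:
    """Clumped protected-area mask covering ``target_fraction`` of the grid.

    Uses the same smoothed-noise thresholding as the landscape generator, so
    the realized fraction is exact up to integer rounding of the cell count.
    Reserves are not sited at random: ``formation_bias`` (in SD units of the
    noise field) shifts the threshold field toward Mediterranean vegetation
    formations, so protected areas preferentially cover natural vegetation —
    as statutory reserves do — while remaining spatially clumped. Set it to
    0 for vegetation-independent placement.
    """
    if not 0 <= target_fraction < 1:
        raise ConfigurationError("target_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    fld = _smooth_field(landscape.shape, 3.0, rng)
    fld = fld / max(fld.std(), 1e-12)
    formation = np.isin(landscape.classes, landscape.registry.formation_codes)
    fld = fld - formation_bias * formation
    n = fld.size
    k = int(round(target_fraction * n))
    mask = np.zeros(n, dtype=bool)
    if k > 0:
        mask[np.argsort(fld, axis=None, kind="stable")[:k]] = True
    return ProtectedAreaMask(mask.reshape(landscape.shape))


# ---------------------------------------------------------------------------
# planning units


@dataclass
class PUGrid:
    """Planning-unit tiling of the raster.

    ``pu_ids`` maps each cell to a PU id (1-based, row-major blocks).
    ``adjacency`` maps ordered pairs (a, b) *and* (b, a) to the shared
    boundary length in km; ``outer_len`` is each PU's exposed length on the
    study-area edge.
    """

    pu_ids: np.ndarray
    ids: np.ndarray
    pu_area: np.ndarray  # km^2, aligned with ids
    adjacency: dict[tuple[int, int], float]
    outer_len: dict[int, float]
    cell_size: float

    @property
    def n_pus(self) -> int:
        return len(self.ids)

    def index_of(self) -> dict[int, int]:
        return {int(p): i for i, p in enumerate(self.ids)}

    def cells_per_pu(self) -> np.ndarray:
        counts = np.bincount(self.pu_ids.ravel())
        return counts[self.ids]

    def neighbors(self, pu: int) -> list[tuple[int, float]]:
        return [(b, L) for (a, b), L in self.adjacency.items() if a == pu]

    def pu_fraction(self, cell_mask: np.ndarray) -> np.ndarray:
        """Fraction of each PU's cells where ``cell_mask`` is True."""
        if cell_mask.shape != self.pu_ids.shape:
            raise AlignmentError("mask shape does not match PU raster")
        tot = np.bincount(self.pu_ids.ravel())
        hit = np.bincount(self.pu_ids.ravel(), weights=cell_mask.ravel().astype(float))
        with np.errstate(invalid="ignore"):
            frac = np.where(tot > 0, hit / np.maximum(tot, 1), 0.0)
        return frac[self.ids]

    def pu_area_of(self, cell_mask: np.ndarray) -> np.ndarray:
        """Area (km^2) of mask-True cells within each PU."""
        if cell_mask.shape != self.pu_ids.shape:
            raise AlignmentError("mask shape does not match PU raster")
        hit = np.bincount(
            self.pu_ids.ravel(), weights=cell_mask.ravel().astype(float)
        )
        hit = np.pad(hit, (0, max(0, int(self.ids.max()) + 1 - len(hit))))
        return hit[self.ids] * self.cell_size**2


def make_pu_grid(
    landscape: LandCoverGrid,
    pu_area: float = 1.0,
    geometry: str = "square",
) -> PUGrid:
    """Tile the raster into square k x k planning units.

    ``pu_area`` must correspond to an integer number of cells per side
    (k = sqrt(pu_area) / cell_size). PUs at the right/bottom edge may be
    truncated; their areas reflect the actual cell count. Adjacency lists
    every PU pair sharing cell edges, with length = shared edges x cell_size.
    """
    if geometry == "hex":
        raise NotImplementedError("hexagonal PU tiling is not implemented; use 'square'")
    if geometry != "square":
        raise ConfigurationError(f"unknown PU geometry {geometry!r}")
    k_f = np.sqrt(pu_area) / landscape.cell_size
    k = int(round(k_f))
    if k < 1 or abs(k_f - k) > 1e-9:
        raise ConfigurationError(
            f"pu_area {pu_area} km^2 is not an integer k x k block of "
            f"{landscape.cell_size} km cells"
        )
    rows, cols = landscape.shape
    bi = np.arange(rows) // k
    bj = np.arange(cols) // k
    nbc = cols // k + (1 if cols % k else 0)
    pu_ids = (bi[:, None] * nbc + bj[None, :] + 1).astype(np.int64)

    ids = np.unique(pu_ids)
    counts = np.bincount(pu_ids.ravel())[ids]
    areas = counts * landscape.cell_area

    cs = landscape.cell_size
    adjacency: dict[tuple[int, int], float] = {}

    def _accumulate(a_vals: np.ndarray, b_vals: np.ndarray) -> None:
        diff = a_vals != b_vals
        if not diff.any():
            return
        pairs = np.stack([a_vals[diff], b_vals[diff]], axis=1)
        uniq, cnt = np.unique(pairs, axis=0, return_counts=True)
        for (a, b), n in zip(uniq, cnt):
            key = (int(a), int(b))
            adjacency[key] = adjacency.get(key, 0.0) + float(n) * cs
            rkey = (int(b), int(a))
            adjacency[rkey] = adjacency.get(rkey, 0.0) + float(n) * cs

    # horizontal and vertical shared edges (each unordered pair accumulated once,
    # mirrored into both orders)
    _accumulate(pu_ids[:, :-1].ravel(), pu_ids[:, 1:].ravel())
    _accumulate(pu_ids[:-1, :].ravel(), pu_ids[1:, :].ravel())

    outer = {int(p): 0.0 for p in ids}
    for border in (pu_ids[0, :], pu_ids[-1, :], pu_ids[:, 0], pu_ids[:, -1]):
        u, c = np.unique(border, return_counts=True)
        for p, n in zip(u, c):
            outer[int(p)] += float(n) * cs

    return PUGrid(
        pu_ids=pu_ids,
        ids=ids,
        pu_area=areas.astype(float),
        adjacency=adjacency,
        outer_len=outer,
        cell_size=cs,
    )
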