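"""The virtual foraging environment.

A toroidal ``width x height`` grid of cells holding "food" particles, plus a
single foraging entity with a position and an 8-way compass heading.  Cells
store particle *counts*: when the entity moves onto a cell with food it eats
(one success event) and the cell's entire content is relocated, each particle
to an independently chosen random square — occupied squares are allowed, so
particles can stack.  The total particle count set at initialisation is
therefore conserved exactly, while the number of *occupied* cells fluctuates
slightly below it.  The entity perceives a 7x7 window of cell occupancies
(the visual field) centred on its own position; offsets wrap around the
torus.

Placement can be uniform or vertically biased: with probability
``vertical_bias`` a new particle lands on an empty cell directly above or
below an existing particle (falling back to uniform if no such cell exists),
which arranges food into vertical columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._rng import STREAM_ENV, random_below, random_float

# 8-way compass directions, clockwise from north.  Row axis points south.
DIRECTION_NAMES = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")
DIR_DR = np.array([-1, -1, 0, 1, 1, 1, 0, -1], dtype=np.int64)
DIR_DC = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)

VISUAL_RADIUS = 3  # the visual field spans offsets -3..+3 in both axes


@dataclass
class FoodDistribution:
    """Food density and (optional) vertical placement bias."""

    density: float = 0.10
    vertical_bias: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"density must lie in [0, 1], got {self.density}")
        if not 0.0 <= self.vertical_bias < 1.0:
            raise ValueError(f"vertical_bias must lie in [0, 1), got {self.vertical_bias}")


@dataclass
class GridWorld:
    """Food particle lattice plus the entity's position and heading."""

    width: int = 50
    height: int = 50
    food: np.ndarray = field(default=None)  # int64 particle counts, (height, width)
    entity_row: int = 0
    entity_col: int = 0
    heading: int = 0  # index into DIRECTION_NAMES

    def __post_init__(self) -> None:
        if self.food is None:
            self.food = np.zeros((self.height, self.width), dtype=np.int64)
        if self.food.shape != (self.height, self.width):
            raise ValueError("food array shape must be (height, width)")
        if not (0 <= self.entity_row < self.height and 0 <= self.entity_col < self.width):
            raise ValueError("entity position outside the grid")

    @property
    def food_count(self) -> int:
        """Total number of food particles (conserved after initialisation)."""
        return int(self.food.sum())

    @property
    def occupied_count(self) -> int:
        """Number of cells holding at least one particle."""
        return int((self.food > 0).sum())


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------
@njit(cache=True)
def place_food_kernel(food, vertical_bias, avoid_row, avoid_col, rng_state) -> None:
    """Drop one particle on a random cell (never on (avoid_row, avoid_col)).

    With probability ``vertical_bias`` the cell is drawn uniformly from the
    empty cells directly above or below an occupied cell (uniform fallback
    when none exists); otherwise from all cells, occupied allowed.
    """
    height, width = food.shape
    if vertical_bias > 0.0 and random_float(rng_state, STREAM_ENV) < vertical_bias:
        # Count empty cells vertically adjacent to food.
        n_cand = 0
        for r in range(height):
            for c in range(width):
                if food[r, c] == 0 and not (r == avoid_row and c == avoid_col):
                    if food[(r - 1) % height, c] > 0 or food[(r + 1) % height, c] > 0:
                        n_cand += 1
        if n_cand > 0:
            k = random_below(rng_state, STREAM_ENV, n_cand)
            for r in range(height):
                for c in range(width):
                    if food[r, c] == 0 and not (r == avoid_row and c == avoid_col):
                        if food[(r - 1) % height, c] > 0 or food[(r + 1) % height, c] > 0:
                            if k == 0:
                                food[r, c] += 1
                                return
                            k -= 1
    # Uniform placement on any cell but the avoided one.
    while True:
        r = random_below(rng_state, STREAM_ENV, height)
        c = random_below(rng_state, STREAM_ENV, width)
        if not (r == avoid_row and c == avoid_col):
            food[r, c] += 1
            return


@njit(cache=True)
def init_food_kernel(food, density, vertical_bias, rng_state) -> int:
    """Fill an empty grid with exactly round(density * cells) particles.

    Initial particles always land on distinct cells (one per cell)."""
    height, width = food.shape
    n_cells = height * width
    n_food = int(round(density * n_cells))
    if vertical_bias == 0.0:
        # Exact-count sampling without replacement: partial Fisher-Yates.
        idx = np.arange(n_cells)
        for i in range(n_food):
            j = i + random_below(rng_state, STREAM_ENV, n_cells - i)
            idx[i], idx[j] = idx[j], idx[i]
            food[idx[i] // width, idx[i] % width] = 1
    else:
        # Sequential placement: each particle is biased toward cells directly
        # above/below already-placed food, falling back to a uniform empty cell.
        for m in range(n_food):
            placed = False
            if m > 0 and random_float(rng_state, STREAM_ENV) < vertical_bias:
                n_cand = 0
                for r in range(height):
                    for c in range(width):
                        if food[r, c] == 0 and (
                            food[(r - 1) % height, c] > 0 or food[(r + 1) % height, c] > 0
                        ):
                            n_cand += 1
                if n_cand > 0:
                    k = random_below(rng_state, STREAM_ENV, n_cand)
                    for r in range(height):
                        if placed:
                            break
                        for c in range(width):
                            if food[r, c] == 0 and (
                                food[(r - 1) % height, c] > 0
                                or food[(r + 1) % height, c] > 0
                            ):
                                if k == 0:
                                    food[r, c] = 1
                                    placed = True
                                    break
                                k -= 1
            while not placed:
                r = random_below(rng_state, STREAM_ENV, height)
                c = random_below(rng_state, STREAM_ENV, width)
                if food[r, c] == 0:
                    food[r, c] = 1
                    placed = True
    return n_food


@njit(cache=True)
def visual_field_kernel(food, entity_row, entity_col, out) -> None:
    """Fill ``out`` (7x7 uint8) with the toroidal occupancy window.

    The centre entry (the entity's own cell) is always 0.
    """
    height, width = food.shape
    for i in range(7):
        for j in range(7):
            r = (entity_row + i - VISUAL_RADIUS) % height
            c = (entity_col + j - VISUAL_RADIUS) % width
            out[i, j] = 1 if food[r, c] > 0 else 0
    out[VISUAL_RADIUS, VISUAL_RADIUS] = 0


@njit(cache=True)
def move_entity_kernel(food, entity_row, entity_col, direction, vertical_bias, rng_state):
    """Move one step in ``direction`` (toroidal); eat-and-relocate food.

    Eating relocates the destination cell's entire content, one random square
    per particle, never onto the entity's new cell.  Returns
    (new_row, new_col, ate).
    """
    height, width = food.shape
    r = (entity_row + DIR_DR[direction]) % height
    c = (entity_col + DIR_DC[direction]) % width
    ate = food[r, c] > 0
    if ate:
        k = food[r, c]
        food[r, c] = 0
        for _ in range(k):
            place_food_kernel(food, vertical_bias, r, c, rng_state)
    return r, c, ate


# ---------------------------------------------------------------------------
# Python-level operations on GridWorld
# ---------------------------------------------------------------------------
def init_food(world: GridWorld, dist: FoodDistribution, rng_state: np.ndarray) -> GridWorld:
    """Distribute food on an empty grid according to ``dist`` (in place)."""
    if world.food_count != 0:
        raise ValueError("init_food requires a world with no food")
    if not 0.0 <= dist.density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {dist.density}")
    init_food_kernel(world.food, dist.density, dist.vertical_bias, rng_state)
    return world


def visual_field(world: GridWorld) -> np.ndarray:
    """The 7x7 boolean occupancy window centred on the entity (centre always False)."""
    out = np.zeros((7, 7), dtype=np.uint8)
    visual_field_kernel(world.food, world.entity_row, world.entity_col, out)
    return out.astype(bool)


def move_entity(
    world: GridWorld,
    direction: int,
    rng_state: np.ndarray,
    dist: FoodDistribution | None = None,
) -> bool:
    """Execute one move (in place); returns True if food was eaten.

    Eaten food is relocated cell-content-wise according to ``dist`` (uniform
    when ``dist`` is None), never onto the entity's new cell.
    """
    if not 0 <= direction < 8:
        raise ValueError(f"direction must be one of 0..7, got {direction}")
    bias = 0.0 if dist is None else dist.vertical_bias
    r, c, ate = move_entity_kernel(
        world.food, world.entity_row, world.entity_col, direction, bias, rng_state
    )
    world.entity_row, world.entity_col = int(r), int(c)
    world.heading = int(direction)
    return bool(ate)


def save_grid_csv(world: GridWorld, path: str) -> None:
    """Write the particle-count lattice as a plain integer CSV matrix."""
    np.savetxt(path, world.food, fmt="%d", delimiter=",")
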