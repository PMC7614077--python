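"""Synthetic embryo simulator.

Generates ground-truth lineage forests with the event types a developing
embryo exhibits between consecutive frames -- movement, division into two,
death, and entry into / exit from the field of view (never merging) -- and
renders them as the dense prediction maps a trained detection network would
produce: a cell-indicator volume peaking at nucleus centers, a per-voxel
movement-vector volume pointing to the same cell in the previous frame, and
a binary foreground mask.  This stands in for network inference so the full
candidate-extraction + ILP pipeline can be exercised at desk scale.

Coordinate convention (used package-wide): positions are ``(t, z, y, x)``,
0-based voxel units; spatial 3-vectors are ordered ``(z, y, x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forest import LineageForest

__all__ = ["SimConfig", "SimulationError", "simulate_lineages", "render_predictions"]


class SimulationError(RuntimeError):
    """Raised when cells cannot be packed at the minimum inter-nucleus distance."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic embryo.

    Probabilities are per cell per frame.  ``step_sigma`` is the standard
    deviation of the isotropic Gaussian displacement per frame, truncated at
    ``max_step`` (voxels); downstream edge-search radii must exceed
    ``max_step`` (documented, not enforced).  ``sigma`` is the per-axis
    (z, y, x) standard deviation of the rendered indicator Gaussian.
    """

    shape: tuple[int, int, int, int] = (30, 20, 64, 64)  # (T, Z, Y, X)
    n_initial: int = 20
    p_divide: float | tuple[float, ...] = 0.02  # scalar, or per-frame sequence
    p_death: float = 0.005
    p_exit: float = 0.005
    entry_rate: float = 0.1  # expected new cells entering per frame (Poisson)
    step_sigma: float = 1.0
    max_step: float = 3.0
    min_distance: float = 6.0
    division_separation: float = 6.0  # distance between daughters
    sigma: tuple[float, float, float] = (1.5, 2.5, 2.5)  # indicator sigma, zyx
    support_factor: float = 2.0  # nucleus support radius = factor * sigma
    margin: float = 3.0  # keep centers this far from spatial borders
    noise_sigma: float = 0.0  # additive indicator noise
    movement_noise_sigma: float = 0.0  # additive movement-vector noise (voxels)
    false_blob_rate: float = 0.0  # expected false blobs per frame (Poisson)
    false_blob_peak_range: tuple[float, float] = (0.2, 0.7)
    seed: int = 0

    def validate(self) -> None:
        p_div = np.atleast_1d(np.asarray(self.p_divide, dtype=float))
        for name, vals in (
            ("p_divide", p_div),
            ("p_death", np.array([self.p_death])),
            ("p_exit", np.array([self.p_exit])),
        ):
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(f"{name}={vals} not a probability")
        if any(s <= 0 for s in self.shape):
            raise ValueError("volume extent must be positive")
        if min(self.sigma) <= 0:
            raise ValueError("sigma must be positive")


def _place(
    rng: np.random.Generator,
    existing: list[np.ndarray],
    lo: np.ndarray,
    hi: np.ndarray,
    min_dist: float,
    tries: int = 200,
) -> np.ndarray | None:
    """Uniform rejection sampling of a point at least min_dist from existing."""
    for _ in range(tries):
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) >= min_dist for q in existing):
            return p
    return None


def simulate_lineages(config: SimConfig) -> LineageForest:
    """Sample a ground-truth binary lineage forest under ``config``.

    Per frame, each live cell first dies with ``p_death``, exits the field of
    view with ``p_exit``, divides with ``p_divide`` (daughters placed
    symmetrically about the mother so both point back at her), and otherwise
    takes a truncated Gaussian step.  New cells enter at Poisson rate
    ``entry_rate``.  No two nuclei in the same frame come closer than
    ``min_distance``.

    Raises :class:`SimulationError` naming the frame if placement fails.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T, Z, Y, X = config.shape
    m = config.margin
    lo = np.array([m, m, m])
    hi = np.array([Z - 1 - m, Y - 1 - m, X - 1 - m])
    if np.any(hi <= lo):
        raise ValueError("volume too small for the configured margin")

    forest = LineageForest()
    next_id = 0

    def fresh() -> int:
        nonlocal next_id
        next_id += 1
        return next_id - 1

    # frame 0: pack initial cells
    placed: list[np.ndarray] = []
    live: list[int] = []  # node ids of cells alive in the current frame
    for _ in range(config.n_initial):
        p = _place(rng, placed, lo, hi, config.min_distance)
        if p is None:
            raise SimulationError(
                f"cannot place {config.n_initial} cells at min distance "
                f"{config.min_distance} in frame 0"
            )
        placed.append(p)
        nid = fresh()
        forest.add_node(nid, 0, p)
        live.append(nid)

    def step(pos: np.ndarray) -> np.ndarray:
        d = rng.normal(0.0, config.step_sigma, size=3)
        norm = np.linalg.norm(d)
        if norm > config.max_step:
            d *= config.max_step / norm
        return np.clip(pos + d, lo, hi)

    p_div_seq = np.atleast_1d(np.asarray(config.p_divide, dtype=float))

    def attempt_frame(t: int, p_divide: float):
        """One draw of all events and placements for frame t.

        Returns ``(births, exited)`` where ``births`` is a list of
        (parent_id or None, position) and ``exited`` the parents flagged as
        leaving the field of view, or ``None`` if placement dead-ends.
        """
        births: list[tuple[int | None, np.ndarray]] = []
        placed: list[np.ndarray] = []
        exited: list[int] = []
        for nid in live:
            pos = forest.nodes[nid].position
            u = rng.uniform()
            if u < config.p_death:
                continue  # cell dies: track ends
            if u < config.p_death + config.p_exit:
                exited.append(nid)
                continue  # cell leaves the field of view
            if u < config.p_death + config.p_exit + p_divide:
                # division: daughters symmetric about the mother
                ok = False
                for _ in range(100):
                    d = rng.normal(0.0, 1.0, size=3)
                    d /= max(np.linalg.norm(d), 1e-12)
                    d *= config.division_separation / 2.0
                    da = np.clip(pos + d, lo, hi)
                    db = np.clip(pos - d, lo, hi)
                    if np.linalg.norm(da - db) < config.min_distance:
                        continue
                    if all(
                        np.linalg.norm(da - q) >= config.min_distance
                        and np.linalg.norm(db - q) >= config.min_distance
                        for q in placed
                    ):
                        ok = True
                        break
                if ok:
                    births += [(nid, da), (nid, db)]
                    placed += [da, db]
                    continue
            # plain movement: Gaussian proposals, then uniform proposals in
            # the step ball when the neighborhood is crowded
            ok = False
            for _ in range(100):
                q = step(pos)
                if all(
                    np.linalg.norm(q - r) >= config.min_distance for r in placed
                ):
                    ok = True
                    break
            if not ok:
                for _ in range(300):
                    d = rng.normal(0.0, 1.0, size=3)
                    d *= (
                        config.max_step
                        * rng.uniform() ** (1 / 3)
                        / max(np.linalg.norm(d), 1e-12)
                    )
                    q = np.clip(pos + d, lo, hi)
                    if all(
                        np.linalg.norm(q - r) >= config.min_distance
                        for r in placed
                    ):
                        ok = True
                        break
            if not ok:
                return None
            births.append((nid, q))
            placed.append(q)
        # field-of-view entries
        for _ in range(rng.poisson(config.entry_rate)):
            p = _place(rng, placed, lo, hi, config.min_distance, tries=50)
            if p is None:
                continue  # too crowded to enter; skip silently
            births.append((None, p))
            placed.append(p)
        return births, exited

    for t in range(1, T):
        p_divide = float(p_div_seq[t] if p_div_seq.size > 1 else p_div_seq[0])
        # rejection sampling at frame level: a dead-ended placement (a cell
        # enclosed by already-placed neighbors) retries the whole frame
        result = None
        for _ in range(20):
            result = attempt_frame(t, p_divide)
            if result is not None:
                break
        if result is None:
            raise SimulationError(
                f"cannot place cells at frame {t} without violating "
                f"min distance {config.min_distance}"
            )
        births, exited = result
        for nid in exited:
            forest.nodes[nid].exited = True
        new_live = []
        for parent_id, pos in births:
            cid = fresh()
            forest.add_node(cid, t, pos, parent_id=parent_id)
            new_live.append(cid)
        live = new_live

    forest.validate(extent=config.shape)
    return forest


def _paint_gaussian(
    vol: np.ndarray, center: np.ndarray, sigma: np.ndarray, peak: float, support: np.ndarray
) -> None:
    """Max-combine an anisotropic Gaussian of height ``peak`` into ``vol``."""
    shape = np.array(vol.shape)
    lo = np.maximum(np.ceil(center - support).astype(int), 0)
    hi = np.minimum(np.floor(center + support).astype(int) + 1, shape)
    if np.any(hi <= lo):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sigma))
    patch = peak * np.exp(-0.5 * q)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    np.maximum(vol[sl], patch, out=vol[sl])


def render_predictions(
    forest: LineageForest, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render network-style prediction volumes for a lineage forest.

    Returns ``(indicator, movement, foreground)``:

    - ``indicator``: float32 ``(T, Z, Y, X)``; at each true center an
      anisotropic Gaussian of peak 1, overlaps combined by maximum; false
      blobs at Poisson rate with sub-unit peaks; optional additive noise.
    - ``movement``: float32 ``(T, Z, Y, X, 3)``; within each nucleus's
      support, the offset (z, y, x) from the cell to its parent's position
      at the previous frame (zero for track starts); voxels claimed by the
      nearest nucleus where supports overlap.
    - ``foreground``: uint8 ``(T, Z, Y, X)``; 1 on the support of every true
      nucleus (false blobs are background).
    """
    config.validate()
    T, Z, Y, X = config.shape
    sigma = np.asarray(config.sigma, dtype=float)
    support = config.support_factor * sigma

    indicator = np.zeros((T, Z, Y, X), dtype=np.float32)
    movement = np.zeros((T, Z, Y, X, 3), dtype=np.float32)
    foreground = np.zeros((T, Z, Y, X), dtype=np.uint8)

    # derive all randomness from the config seed, offset so that the forest
    # sampled from the same seed is not replayed
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x52454E44]))

    for t in range(T):
        cells = forest.nodes_at(t)
        # nearest-cell ownership for overlapping supports
        claim = np.full((Z, Y, X), np.inf, dtype=np.float32)
        for n in cells:
            c = n.position
            if np.any(c < 0) or np.any(c >= [Z, Y, X]):
                continue
            _paint_gaussian(indicator[t], c, sigma, 1.0, support)
            par = forest.parent.get(n.node_id)
            offset = (
                forest.nodes[par].position - c if par is not None else np.zeros(3)
            )
            lo = np.maximum(np.ceil(c - support).astype(int), 0)
            hi = np.minimum(np.floor(c + support).astype(int) + 1, [Z, Y, X])
            if np.any(hi <= lo):
                continue
            grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            q = sum(((g - cc) / s) ** 2 for g, cc, s in zip(grids, c, support))
            inside = q <= 1.0
            sl = tuple(slice(l, h) for l, h in zip(lo, hi))
            closer = inside & (q < claim[sl])
            claim[sl] = np.where(closer, q, claim[sl])
            for k in range(3):
                movement[t][sl + (k,)] = np.where(
                    closer, offset[k], movement[t][sl + (k,)]
                )
            foreground[t][sl] |= inside.astype(np.uint8)

        # false blobs: unconstrained-background stand-ins, indicator only
        for _ in range(rng.poisson(config.false_blob_rate)):
            c = rng.uniform([0, 0, 0], [Z - 1, Y - 1, X - 1])
            if cells and min(
                np.linalg.norm(c - n.position) for n in cells
            ) < config.min_distance:
                continue
            peak = rng.uniform(*config.false_blob_peak_range)
            _paint_gaussian(indicator[t], c, sigma, peak, support)

    if config.noise_sigma > 0:
        indicator += rng.normal(0.0, config.noise_sigma, indicator.shape).astype(
            np.float32
        )
        np.clip(indicator, 0.0, 1.0, out=indicator)
    if config.movement_noise_sigma > 0:
        movement += rng.normal(
            0.0, config.movement_noise_sigma, movement.shape
        ).astype(np.float32)

    return indicator, movement, foreground
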