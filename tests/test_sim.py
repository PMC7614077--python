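"""Simulator: event statistics, rendering geometry, determinism."""

import numpy as np
import pytest
from scipy import stats

from ilptrack import (
    SimConfig,
    SimulationError,
    render_predictions,
    simulate_lineages,
)

QUIET = dict(p_divide=0.0, p_death=0.0, p_exit=0.0, entry_rate=0.0)


def test_no_events_gives_pure_movement_tracks():
    config = SimConfig(shape=(10, 16, 48, 48), n_initial=5, seed=1, **QUIET)
    forest = simulate_lineages(config)
    assert len(forest) == 50
    assert forest.n_edges == 45
    assert len(forest.roots()) == 5
    assert forest.divisions() == []
    # consecutive positions differ by less than the max displacement
    for child, parent in forest.parent.items():
        d = np.linalg.norm(
            forest.nodes[child].position - forest.nodes[parent].position
        )
        assert d <= config.max_step + 1e-9


def test_forced_division_yields_two_children():
    p_div = [0.0] * 6
    p_div[3] = 1.0
    config = SimConfig(
        shape=(6, 16, 48, 48),
        n_initial=1,
        seed=2,
        p_divide=tuple(p_div),
        p_death=0.0,
        p_exit=0.0,
        entry_rate=0.0,
    )
    forest = simulate_lineages(config)
    (mother,) = [n for n in forest.nodes if forest.nodes[n].t == 2]
    children = forest.children(mother)
    assert len(children) == 2
    # daughters are symmetric about the mother at the configured separation
    pa, pb = (forest.nodes[c].position for c in children)
    assert np.linalg.norm(pa - pb) == pytest.approx(config.division_separation)
    assert np.allclose((pa + pb) / 2, forest.nodes[mother].position, atol=1e-9)


def test_division_count_within_binomial_interval():
    config = SimConfig(
        shape=(30, 20, 64, 64),
        n_initial=20,
        seed=1,
        p_divide=0.02,
        p_death=0.0,
        p_exit=0.0,
        entry_rate=0.0,
    )
    forest = simulate_lineages(config)
    # every node before the final frame draws one event; divisions are
    # binomial over those draws
    final_t = config.shape[0] - 1
    n_draws = sum(1 for n in forest.nodes.values() if n.t < final_t)
    n_div = len(forest.divisions())
    lo = stats.binom.ppf(0.005, n_draws, 0.02)
    hi = stats.binom.ppf(0.995, n_draws, 0.02)
    assert lo <= n_div <= hi


def test_min_distance_and_extent_respected():
    config = SimConfig(shape=(12, 16, 48, 48), n_initial=10, seed=3)
    forest = simulate_lineages(config)
    forest.validate(extent=config.shape)
    for t in forest.frames():
        pos = np.array([n.position for n in forest.nodes_at(t)])
        if len(pos) > 1:
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= config.min_distance - 1e-9


def test_infeasible_packing_raises_with_frame():
    config = SimConfig(shape=(3, 8, 12, 12), n_initial=50, min_distance=6.0, seed=0)
    with pytest.raises(SimulationError, match="frame 0"):
        simulate_lineages(config)


def test_render_stationary_cell_at_integer_center():
    config = SimConfig(shape=(2, 16, 32, 32), n_initial=1, seed=0, **QUIET)
    forest = simulate_lineages(config)
    # overwrite with a known integer center that does not move
    for n in forest.nodes.values():
        n.position = np.array([8.0, 16.0, 16.0])
    indicator, movement, foreground = render_predictions(forest, config)
    assert indicator[1, 8, 16, 16] == pytest.approx(1.0)
    assert movement[1, 8, 16, 16].tolist() == [0.0, 0.0, 0.0]
    assert foreground[1, 8, 16, 16] == 1


def test_render_movement_vector_is_parent_minus_child():
    config = SimConfig(shape=(2, 16, 40, 40), n_initial=1, seed=0, **QUIET)
    forest = simulate_lineages(config)
    ids = sorted(forest.nodes)
    forest.nodes[ids[0]].position = np.array([10.0, 20.0, 27.0])  # parent, t=0
    forest.nodes[ids[1]].position = np.array([10.0, 20.0, 30.0])  # child, t=1
    _, movement, _ = render_predictions(forest, config)
    assert movement[1, 10, 20, 30].tolist() == [0.0, 0.0, -3.0]
    # frame-0 cells carry the zero vector
    assert movement[0, 10, 20, 27].tolist() == [0.0, 0.0, 0.0]


def test_render_gaussian_decay_one_sigma():
    config = SimConfig(
        shape=(1, 16, 32, 32), n_initial=1, seed=0, sigma=(2.0, 2.0, 2.0), **QUIET
    )
    forest = simulate_lineages(config)
    for n in forest.nodes.values():
        n.position = np.array([8.0, 16.0, 16.0])
    indicator, _, _ = render_predictions(forest, config)
    # one sigma along z: exp(-1/2)
    assert indicator[0, 10, 16, 16] == pytest.approx(np.exp(-0.5), abs=1e-6)


def test_render_peaks_coincide_with_forest_positions(small_sim):
    config, forest, indicator, _, _ = small_sim
    for n in forest.nodes.values():
        voxel = np.round(n.position).astype(int)
        patch = indicator[
            n.t,
            max(voxel[0] - 1, 0) : voxel[0] + 2,
            max(voxel[1] - 1, 0) : voxel[1] + 2,
            max(voxel[2] - 1, 0) : voxel[2] + 2,
        ]
        assert indicator[(n.t, *voxel)] == patch.max()


def test_false_blob_peaks_below_one():
    config = SimConfig(
        shape=(6, 16, 48, 48),
        n_initial=4,
        seed=4,
        false_blob_rate=2.0,
        false_blob_peak_range=(0.2, 0.7),
        **QUIET,
    )
    forest = simulate_lineages(config)
    indicator, _, foreground = render_predictions(forest, config)
    # outside the foreground (no true nucleus), blob peaks stay sub-unit
    background = indicator[foreground == 0]
    assert background.max() <= 0.7 + 1e-6


def test_simulation_and_rendering_deterministic():
    config = SimConfig(
        shape=(8, 16, 48, 48), n_initial=6, seed=11, noise_sigma=0.05,
        movement_noise_sigma=0.5, false_blob_rate=0.5,
    )
    f1 = simulate_lineages(config)
    f2 = simulate_lineages(config)
    assert f1.to_dataframe().equals(f2.to_dataframe())
    r1 = render_predictions(f1, config)
    r2 = render_predictions(f2, config)
    for a, b in zip(r1, r2):
        assert np.array_equal(a, b)


def test_invalid_probability_rejected():
    with pytest.raises(ValueError, match="probability"):
        SimConfig(p_divide=1.5).validate()
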