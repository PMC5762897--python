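"""Self-validation benchmarks run against synthetic ground truth.

The frontier-accuracy benchmark mirrors the software validation of the
original analysis program: automated frontier measurements are compared
against the exact (manual-equivalent) ground truth on a noisy synthetic
device, and the median relative discrepancy is reported.  The device is
scaled to 240 channels (120 per side) with ~4 cells per channel, a
two-component frontier distribution (10% of cells reaching the channel
exit, the rest uniform between 50 and 950 µm), 10% dead cells, debris, and
additive Gaussian read noise.
"""

from __future__ import annotations

import numpy as np

from .chipmodel import DeviceGeometry, ground_truth_frontiers, render, sample_scene
from .quantify import QuantConfig, quantify_device, results_to_frame

__all__ = ["frontier_accuracy_benchmark"]


def frontier_accuracy_benchmark(
    seed: int,
    n_channels_per_side: int = 120,
    n_cells: int = 960,
    noise_sd: float = 10.0,
    migratory_fraction: float = 0.1,
    dead_fraction: float = 0.1,
    debris_count: int = 60,
    min_frontier_um: float = 50.0,
    config: QuantConfig | None = None,
) -> dict:
    """Median relative frontier error (%) of the pipeline vs ground truth.

    Generates one synthetic device, runs the full quantification pipeline
    with default detection settings, and compares per-channel frontier
    distances with the generator's ground truth over channels whose true
    frontier is at least ``min_frontier_um``.  Returns a dict with the
    median relative error in percent, the per-channel errors, and the
    number of channels scored.
    """
    geometry = DeviceGeometry(n_channels_per_side=n_channels_per_side)
    scene = sample_scene(
        geometry,
        n_cells=n_cells,
        distance_dist="two_component",
        dist_params={
            "migratory_fraction": migratory_fraction,
            "low": min_frontier_um,
            "high": geometry.channel_length_um - 50.0,
        },
        dead_fraction=dead_fraction,
        debris_count=debris_count,
        noise_sd=noise_sd,
        seed=seed,
    )
    config = config or QuantConfig(central_window=n_channels_per_side)
    image = render(scene)
    measured = results_to_frame(quantify_device(image, geometry, config))
    truth = ground_truth_frontiers(scene)
    merged = measured.merge(
        truth, on=["channel_index", "side"], suffixes=("", "_truth")
    )
    scored = merged[merged["frontier_distance_um_truth"] >= min_frontier_um]
    rel_err = (
        (scored["frontier_distance_um"] - scored["frontier_distance_um_truth"]).abs()
        / scored["frontier_distance_um_truth"]
    ).to_numpy()
    return {
        "median_relative_error_pct": float(np.median(rel_err) * 100.0),
        "relative_errors": rel_err,
        "n_channels_scored": int(len(scored)),
        "n_channels_total": int(len(merged)),
    }
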