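"""CSV/JSON writers and test-fixture generation.

The CSV dialect is fixed for reproducibility: comma separator, '.' decimal,
LF line endings, exactly one header row.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .dispersion import DispersionBranch, group_velocity
from .saltatory_sim import FiringTimeline

DISPERSION_COLUMNS = ("k_per_m", "kd", "re_omega", "im_omega",
                      "vg_m_per_s", "converged", "polarization")


def write_dispersion_csv(path, branch: DispersionBranch) -> None:
    """One row per k grid point, columns fixed by DISPERSION_COLUMNS.

    Light-cone-excluded grid points are written as rows with NaN omega and
    converged = 0, so the row count always equals the requested grid size.
    """
    vg = branch.v_g if branch.v_g is not None else group_velocity(branch)
    d = branch.geometry.period
    rows = [(float(k), float(om.real), float(om.imag), float(v), int(conv))
            for k, om, v, conv in zip(branch.k, branch.omega, vg,
                                      branch.converged)]
    rows += [(float(k), float("nan"), float("nan"), float("nan"), 0)
             for k in branch.excluded_k]
    rows.sort(key=lambda r: r[0])
    with open(path, "w", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(DISPERSION_COLUMNS)
        for k, re_om, im_om, v, conv in rows:
            w.writerow([repr(k), repr(k * d), repr(re_om), repr(im_om),
                        repr(v), conv, branch.polarization])


def write_beat_csv(path, xi_grid, beat, omega1_eff) -> None:
    with open(path, "w", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(("xi_m", "beat_rad_per_s", "omega1_eff_rad_per_s"))
        for row in zip(xi_grid, beat, omega1_eff):
            w.writerow([repr(float(v)) for v in row])


def write_timeline_json(path, timeline: FiringTimeline) -> None:
    obj = {
        "params": {
            "n_nodes": timeline.n_nodes,
            "segment_length_m": timeline.segment_length,
            "packet_velocity_m_per_s": timeline.packet_velocity,
            "origin": timeline.origin,
            "duration_s": timeline.duration,
            "hh_spike_duration_s": timeline.hh_spike_duration,
            "refractory_s": timeline.refractory,
            "damaged": sorted(timeline.damaged_set),
            "breaks": [list(b) for b in timeline.break_set],
        },
        "events": [{"t": t, "node": j, "transition": tr}
                   for t, j, tr in timeline.events],
        "counts": {"ignited": len(timeline.ignition_times)},
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def write_timeline_csv(path, timeline: FiringTimeline) -> None:
    with open(path, "w", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(("t_s", "node", "transition"))
        for t, j, tr in timeline.events:
            w.writerow([repr(float(t)), j, tr])


def generate_fixtures(seed: int) -> dict:
    """Seed-reproducible parameter sets for property tests.

    Returns the two shipped presets plus randomized-but-valid draws
    (each nominal value jittered by up to +-10%).
    """
    from .axon_presets import load_preset

    rng = np.random.default_rng(seed)

    def jitter(value):
        return float(value * (1.0 + 0.1 * rng.uniform(-1.0, 1.0)))

    draws = []
    for _ in range(8):
        a = jitter(50e-6)
        draws.append({
            "segment_radius_m": a,
            "period_m": a * jitter(2.2),
            "eps": jitter(80.0),
            "omega1_rad_per_s": jitter(4e6),
            "inv_tau0_per_s": abs(jitter(1e3)),
            "ion_charge_c": jitter(1.6e-19),
            "ion_mass_kg": jitter(9.1e-27),
            "concentration_per_m3": jitter(2.1e16),
            "temperature_k": jitter(300.0),
            "mean_free_path_m": jitter(1e-9),
        })
    return {
        "presets": {name: load_preset(name) for name in ("myelinated_pns", "c_fibre")},
        "random_draws": draws,
        "seed": seed,
    }
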