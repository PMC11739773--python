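"""Synthetic patients with known ground truth.

Each synthetic subject is a desk-scale 2D ventricular slab carrying an
infarct: a transmural core band anchored across the slab with a
configurable number of border-zone channels traversing it (the conducting
corridors that anchor reentry), plus a nodal signal-intensity field
constructed so that full-width-half-maximum labeling reproduces the scar
geometry (exactly in noise-free mode).  Event histories follow a
proportional-hazards model whose log-hazard is linear in the computed
imaging/simulation metrics, so downstream statistics can be validated
against known effect sizes.

Randomness is fully deterministic: one global seed expands to per-subject
seeds through numpy's SeedSequence spawning (seed, subject index).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import lge, vita
from .eikonal import VelocityModel
from .geometry import assign_aha_and_pacing, assign_fibers, build_slab
from .model import BZ, CORE, HEALTHY, ScarSpec, VentricularModel

#: nodal intensity levels (arbitrary units): core / border zone / healthy.
#: With FWHM thresholds (0.40, 0.60) of max=100 these map back exactly.
INTENSITY_CORE = 100.0
INTENSITY_BZ = 50.0
INTENSITY_HEALTHY = 10.0

METRIC_COLUMNS = [
    "bz_g", "core_g", "total_enhancement_g", "total_corridors",
    "corridor_weight_g", "interface_healthy_scar_cm2", "interface_bz_core_cm2",
    "total_vts", "unique_vts", "mean_rtt_ms", "max_rtt_ms",
]

CLINICAL_COLUMNS = ["lvef_pct", "lvedv_ml", "prevention_secondary"]


@dataclass
class CohortSpec:
    """Study-condition parameters for a synthetic cohort.

    The defaults describe a post-infarct ICD cohort: ~40% event fraction
    over a multi-year follow-up window, scars with 0-3 conducting
    corridors, and slowed border-zone conduction.
    """

    n_subjects: int = 40
    seed: int = 0
    # scar anatomy (slab: 40 x 40 mm, 1 mm edges)
    slab_mm: float = 40.0
    edge_len_mm: float = 1.0
    core_height_range: tuple = (8.0, 12.0)
    channel_count_probs: tuple = (0.2, 0.35, 0.3, 0.15)  # P(k = 0..3)
    channel_width_range: tuple = (2.5, 4.0)
    # electrophysiology
    velocity: VelocityModel = field(default_factory=VelocityModel)
    n_pacing_sites: int = 8
    rtt_min_ms: float = vita.RTT_MIN_MS
    rho_dup: float = vita.RHO_DUP
    # event model: exponential baseline, log-hazard linear in standardized
    # metrics, uniform censoring over the follow-up window
    baseline_hazard_per_year: float = 0.15
    beta_per_sd: dict = field(
        default_factory=lambda: {
            "interface_healthy_scar_cm2": np.log(1.8),
            "mean_rtt_ms": np.log(1.6),
        }
    )
    censoring_window_years: float = 6.0
    # intensity noise (0 = exact label/intensity round trip)
    intensity_noise_sd: float = 0.0
    # metric source: "pipeline" computes lge+vita per subject; "sampled"
    # draws metrics from Table-2-like parametric distributions (for
    # large-n statistical validation where meshing every subject adds
    # nothing to the property under test)
    metrics_mode: str = "pipeline"

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.baseline_hazard_per_year <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.censoring_window_years < 0:
            raise ValueError("censoring window must be >= 0")


def subject_rng(spec: CohortSpec, subject: int) -> np.random.Generator:
    """Per-subject generator: deterministic from (seed, subject index)."""
    return np.random.default_rng(np.random.SeedSequence((spec.seed, subject)))


# ----------------------------------------------------------------------
# geometry + intensity


def _sample_scar(spec: CohortSpec, rng: np.random.Generator):
    """Core band anchored at the left wall with k non-touching channels.

    The band stops short of the right wall, leaving a conducting margin:
    every channel therefore participates in at least one reentrant loop
    (through the channel and back around the free end), and adding
    channels adds loops.
    """
    L = spec.slab_mm
    h = rng.uniform(*spec.core_height_range)
    cy = L / 2.0
    k = int(rng.choice(len(spec.channel_count_probs), p=spec.channel_count_probs))
    # ordered positions with a guaranteed minimum gap (no rejection loop)
    lo, hi, gap = 6.0, L - 12.0, 8.0
    slack = hi - lo - gap * max(k - 1, 0)
    u = np.sort(rng.uniform(0.0, 1.0, size=k))
    xs = [float(round(lo + slack * ui + gap * j)) for j, ui in enumerate(u)]
    widths = [float(rng.uniform(*spec.channel_width_range)) for _ in range(k)]
    channels = [
        (np.array([[x, cy - h], [x, cy + h]]), w) for x, w in zip(xs, widths)
    ]
    band_right = L - 6.0  # conducting margin at the right wall
    scar = ScarSpec(
        core_regions=[
            ("box", ((band_right - 2.0) / 2 - 1.0, cy, 0.0), (band_right + 2.0, h, 0.0))
        ],
        bz_rim_width=0.0,
        channels=channels,
    )
    return scar, {"core_height_mm": h, "n_channels": k,
                  "channel_x_mm": xs, "channel_width_mm": widths}


def intensity_from_scar(
    model: VentricularModel, scar: ScarSpec, noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Nodal intensity field encoding the scar geometry.

    Channel nodes take the border-zone level even inside core regions
    (the corridor is viable tissue); core nodes the maximum level; the
    rest healthy.  Optional Gaussian nodal noise emulates imaging noise.
    """
    pts = model.nodes
    inten = np.full(model.n_nodes, INTENSITY_HEALTHY)
    core_d = scar.core_distance(pts)
    inten[core_d <= 0] = INTENSITY_CORE
    if scar.bz_rim_width > 0:
        inten[(core_d > 0) & (core_d <= scar.bz_rim_width)] = INTENSITY_BZ
    ch = scar.channel_mask(pts)
    inten[ch & (core_d <= 0)] = INTENSITY_BZ
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requires an explicit rng")
        inten = np.clip(inten + rng.normal(0, noise_sd, model.n_nodes), 0, None)
    return inten


def generate_subject(spec: CohortSpec, subject: int):
    """One synthetic subject: labeled model + intensity field + truth dict.

    The model's tissue labels are defined as the FWHM labeling of the
    subject's intensity field, so the label/intensity round trip is exact
    by construction in noise-free mode.
    """
    rng = subject_rng(spec, subject)
    scar, truth = _sample_scar(spec, rng)
    model = build_slab(spec.slab_mm, spec.slab_mm, 0.0, spec.edge_len_mm)
    inten = intensity_from_scar(model, scar, spec.intensity_noise_sd, rng)
    model.tissue = lge.fwhm_label(model, inten)
    assign_fibers(model, 0.0, 0.0)
    return model, inten, truth


def _pipeline_metrics(spec: CohortSpec, model: VentricularModel) -> dict:
    img = lge.imaging_metrics(model)
    _, sites = assign_aha_and_pacing(model, spec.n_pacing_sites)
    met, _, _ = vita.run_vita(
        model, spec.velocity, sites,
        rtt_min_ms=spec.rtt_min_ms, rho_dup=spec.rho_dup,
    )
    out = img.as_dict()
    out.pop("masses_2d_nominal", None)
    out.update(met.as_dict())
    return out


def _sampled_metrics(rng: np.random.Generator) -> dict:
    """Metric panel drawn from parametric distributions with magnitudes
    comparable to a post-infarct ICD cohort (used for large-n statistical
    validation only; the pipeline never sees these at test time)."""
    shared = rng.normal()  # common scar-burden factor couples the panel
    bz = float(np.exp(np.log(10.0) + 0.45 * shared + 0.25 * rng.normal()))
    core = float(np.exp(np.log(6.5) + 0.5 * shared + 0.3 * rng.normal()))
    corridors = int(rng.poisson(np.exp(1.3 + 0.4 * shared)))
    cw = float(np.exp(np.log(1.8) + 0.5 * shared + 0.4 * rng.normal()))
    ihs = float(np.clip(88 + 25 * shared + 18 * rng.normal(), 8, None))
    ibc = float(np.clip(63 + 20 * shared + 16 * rng.normal(), 5, None))
    tv = int(rng.poisson(np.exp(3.2 + 0.6 * shared)))
    uv = int(rng.binomial(max(tv, 1), 0.15))
    mean_rtt = float(np.clip(95 + 30 * shared + 25 * rng.normal(), 55, None))
    max_rtt = float(mean_rtt * (1.0 + rng.gamma(2.0, 0.25)))
    return {
        "bz_g": bz, "core_g": core, "total_enhancement_g": bz + core,
        "total_corridors": corridors, "corridor_weight_g": cw,
        "interface_healthy_scar_cm2": ihs, "interface_bz_core_cm2": ibc,
        "total_vts": tv, "unique_vts": uv,
        "mean_rtt_ms": mean_rtt, "max_rtt_ms": max_rtt,
    }


def _clinical_covariates(rng: np.random.Generator) -> dict:
    return {
        "lvef_pct": float(np.clip(rng.normal(32, 8), 15, 50)),
        "lvedv_ml": float(np.clip(rng.normal(220, 55), 120, 420)),
        "prevention_secondary": int(rng.random() < 0.35),
    }


def generate_cohort(spec: CohortSpec):
    """Cohort table + ground truth, reproducible from the spec seed.

    Per subject: sample scar anatomy, obtain the 11 imaging/simulation
    metrics (full pipeline or parametric sampling per `metrics_mode`),
    draw clinical covariates, then simulate the event process: event time
    exponential with hazard lambda0 * exp(beta' z) where z holds the
    metrics standardized over the cohort, censoring uniform over the
    follow-up window.
    """
    rows, truths = [], []
    for i in range(spec.n_subjects):
        # clinical covariates come from a separate child stream so they are
        # independent of the scar-anatomy draws that share (seed, i)
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, i, 1)))
        try:
            if spec.metrics_mode == "pipeline":
                model, _, truth = generate_subject(spec, i)
                metrics = _pipeline_metrics(spec, model)
            elif spec.metrics_mode == "sampled":
                _, truth = _sample_scar(spec, subject_rng(spec, i))
                metrics = _sampled_metrics(rng)
            else:
                raise ValueError(f"unknown metrics_mode {spec.metrics_mode!r}")
        except ValueError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"subject {i} failed ({exc}); dropped")
            continue
        row = {"id": i, **metrics, **_clinical_covariates(rng)}
        rows.append(row)
        truths.append({"id": i, **truth})
    table = pd.DataFrame(rows)
    truth_df = pd.DataFrame(truths)

    # standardized linear predictor on the realized cohort
    eta = np.zeros(len(table))
    for col, b in spec.beta_per_sd.items():
        v = table[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd > 0:
            eta += b * (v - v.mean()) / sd
    lam = spec.baseline_hazard_per_year * np.exp(eta)

    ev_rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1 << 20)))
    t_event = ev_rng.exponential(1.0 / lam)
    t_cens = ev_rng.uniform(0.0, max(spec.censoring_window_years, 1e-12), len(table))
    event = (t_event <= t_cens).astype(int)
    table["event"] = event
    table["time_years"] = np.where(event == 1, t_event, t_cens)
    truth_df["linear_predictor"] = eta
    truth_df["event_time_years"] = t_event
    return table, truth_df


def write_cohort(table: pd.DataFrame, truth: pd.DataFrame, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    table.to_csv(os.path.join(out_dir, "cohort.csv"), index=False,
                 float_format="%.6f")
    truth.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False,
                 float_format="%.6f")


# ----------------------------------------------------------------------
# canonical fixture geometries


def canonical_fixtures() -> dict:
    """The canonical test geometries used across modules, with analytic
    reference values.  Returns {name: (builder, manifest)} where builder
    is a zero-argument callable producing the labeled model."""
    from .geometry import build_annulus, build_disc, build_ellipsoid_lv

    fx = {}

    fx["slab_homogeneous"] = (
        lambda: build_slab(40, 40, 0, 0.5),
        {"note": "isotropic propagation oracle; T = distance / v"},
    )

    fx["disc_core_r9_rim11"] = (
        lambda: build_disc(
            11.0, 0.5,
            ScarSpec(core_regions=[("ellipsoid", (0, 0, 0), (9.0, 9.0, 1e9))]),
        ),
        {
            "analytic_loop_ms_at_v0.5": 2 * np.pi * 9.0 / 0.5,
            "note": "single isthmus diametrically opposite any rim pacing site",
        },
    )

    fx["annulus_r9_r11"] = (
        lambda: build_annulus(9.0, 11.0, 0.5),
        {"analytic_loop_ms_at_v0.5": 2 * np.pi * 9.0 / 0.5},
    )

    fx["slab_central_core"] = (
        lambda: build_slab(
            40, 40, 0, 1.0,
            ScarSpec(core_regions=[("box", (20, 20, 0), (10, 10, 0))]),
        ),
        {"expected_isthmus_clusters": 1},
    )

    fx["slab_single_channel"] = (
        lambda: build_slab(
            40, 40, 0, 1.0,
            ScarSpec(
                core_regions=[("box", (8, 20, 0), (18.5, 10, 0))],
                channels=[(np.array([[8.0, 10.0], [8.0, 30.0]]), 3.0)],
            ),
        ),
        {"expected_isthmus_clusters": 1, "expected_corridors": 1},
    )

    fx["slab_two_channels"] = (
        lambda: build_slab(
            40, 40, 0, 1.0,
            ScarSpec(
                core_regions=[
                    ("box", (9, 20, 0), (20, 10, 0)),
                    ("box", (31, 20, 0), (20, 10, 0)),
                ],
                channels=[
                    (np.array([[9.0, 10.0], [9.0, 30.0]]), 3.0),
                    (np.array([[31.0, 10.0], [31.0, 30.0]]), 3.0),
                ],
            ),
        ),
        {"expected_isthmus_clusters": 2, "expected_corridors": 2},
    )

    fx["block_plane_z5"] = (
        lambda: build_slab(
            20, 20, 10, 1.0,
            ScarSpec(core_regions=[("box", (10, 10, 7.5), (24, 24, 5))]),
        ),
        {"analytic_interface_cm2": 4.0,
         "note": "planar healthy|core interface at z = 5"},
    )

    fx["block_spherical_core"] = (
        lambda: build_slab(
            24, 24, 24, 0.75,
            ScarSpec(core_regions=[("ellipsoid", (12, 12, 12), (10, 10, 10))]),
        ),
        {"analytic_interface_cm2": 4 * np.pi,
         "note": "sphere r = 10 mm inside a healthy block"},
    )

    fx["lv_idealized"] = (
        lambda: build_ellipsoid_lv(60.0, 30.0, 9.0, 2.5),
        {"expected_pacing_sites": 17},
    )

    return fx


def make_fixture_suite(out_dir: str) -> dict:
    """Write the canonical geometries as CARP text + manifest.json."""
    from .io import write_carp

    os.makedirs(out_dir, exist_ok=True)
    manifest = {}
    for name, (builder, meta) in canonical_fixtures().items():
        model = builder()
        assign_fibers(model, 0.0, 0.0) if model.kind != "lv" else assign_fibers(model)
        d = os.path.join(out_dir, name)
        write_carp(model, d)
        manifest[name] = {
            "n_nodes": model.n_nodes,
            "n_elements": model.n_elements,
            **{k: (v if not isinstance(v, float) else round(v, 6))
               for k, v in meta.items()},
        }
    with open(os.path.join(out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
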