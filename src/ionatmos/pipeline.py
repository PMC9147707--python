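"""End-to-end pipeline driver: synthetic rigid/flexible scene pair through
density, entropy, diffusion, energetics, PMF and effect-size stages.

Every stage writes CSV/JSON artifacts into the output directory; a manifest
records the package version, config hash, seed and SHA-256 of every output
file, so a rerun at the same seed can be checked for bit-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .density import radial_profile, voxel_number_density
from .dynamics import (
    block_consistency_filter,
    local_diffusion_map,
    merge_sites,
    residence_times,
)
from .energetics import LJParameterSet, lj_decomposition, lj_difference, voxel_energy_map
from .entropy import entropy_difference
from .geometry import (
    GridSpec,
    HelicalFrame,
    HelixSpec,
    ZoneMask,
    assign_zones,
    groove_mask,
)
from .io import RunConfig
from .pmf import (
    accumulate_bins,
    convergence_diagnostics,
    integrate_pmf,
    stitch_windows,
)
from .stats import zone_comparison_report
from .synthetic import (
    GrooveShellMobility,
    SyntheticScene,
    force_samples_from_potential,
    helical_surface_charges,
    simulate_ion_cloud,
    write_scene,
)

log = logging.getLogger("ionatmos")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def build_scene(config: RunConfig, mode: str, seed: int) -> SyntheticScene:
    """Synthetic paired-cylinder scene from the config, rigid or flexible."""
    sc = config["scene"]
    box = tuple(float(b) for b in sc["box"])
    d = float(sc["d"])
    cx1 = (box[0] - d) / 2.0
    cx2 = cx1 + d
    axis_y = box[1] / 2.0
    pos1, q1 = helical_surface_charges((cx1, axis_y), box[2])
    pos2, q2 = helical_surface_charges((cx2, axis_y), box[2])
    positions = np.concatenate([pos1, pos2])
    charges = np.concatenate([q1, q2])
    n_cl = int(sc["n_cl"])
    n_na = int(sc["n_na"])
    scene = SyntheticScene(
        box_lengths=box,
        cylinder_centers=(cx1, cx2),
        cylinder_radius=float(sc["radius"]),
        axis_y=axis_y,
        surface_charge_positions=positions,
        surface_charges=charges,
        ion_counts={"na": n_na, "cl": n_cl},
        mobility_map=GrooveShellMobility(
            [(cx1, axis_y), (cx2, axis_y)],
            d_slow=float(sc["d_slow"]),
            d_fast=float(sc["d_fast"]),
        ),
        flexibility_mode=mode,
        jitter_amplitude=float(sc["jitter_amplitude"]),
        jitter_tau=float(sc["jitter_tau"]),
        frame_interval=float(sc["frame_interval"]),
        n_frames=int(sc["n_frames"]),
        seed=seed,
    )
    scene._n_dna1 = len(pos1)
    return scene


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _groove_zone_of_sites(sites_xyz, hframe, helix, grid, zones: ZoneMask):
    """Zone label (minor/major/interface/other) for each site position."""
    out = []
    c1 = hframe.mean_center(1)
    c2 = hframe.mean_center(2)
    for p in np.atleast_2d(sites_xyz):
        r1 = np.hypot(p[0] - c1[0], p[1] - c1[1])
        r2 = np.hypot(p[0] - c2[0], p[1] - c2[1])
        k = 1 if r1 <= r2 else 2
        c = c1 if k == 1 else c2
        flat, mask = zones.grid.voxel_index(p[None, :])
        zone_lbl = (
            {0: "inside1", 1: "inside2", 2: "interface", 3: "noninterface1",
             4: "noninterface2"}[int(zones.labels[flat[0]])]
            if mask[0]
            else "outside"
        )
        if zone_lbl == "interface":
            out.append("interface")
            continue
        phi = np.arctan2(p[1] - c[1], p[0] - c[0])
        t1, _ = helix.strand_angles(p[2], duplex=k)
        width = np.deg2rad(np.mod(helix.phase2 - helix.phase1, 360.0))
        minor = np.mod(phi - t1, 2 * np.pi) < width
        out.append("minor" if minor else "major")
    return np.asarray(out, dtype=object)


def run_pipeline(config: RunConfig, outdir, stages=None) -> dict:
    """Run the enabled stages and return the manifest dict.

    ``stages`` optionally restricts execution to a subset (the synthetic
    scene pair is always generated; it seeds every stage).  Any stage
    error aborts with the stage name; earlier outputs stay on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["run"]["seed"])
    rng_seed = seed % (2**31 - 1)
    level = getattr(logging, str(config["run"].get("log_level", "info")).upper(), 20)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(name)s %(levelname)s %(message)s")

    all_stages = ["density", "entropy", "diffusion", "energetics", "pmf", "stats"]
    enabled = [
        s for s in all_stages
        if config[s]["enabled"] and (stages is None or s in stages)
    ]
    manifest = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": seed,
        "stages": enabled,
        "files": {},
    }
    (outdir / "config.json").write_text(config.to_json())

    t0 = time.time()
    scene_r = build_scene(config, "rigid", rng_seed)
    scene_f = build_scene(config, "flexible", rng_seed + 1)
    traj = {"rigid": simulate_ion_cloud(scene_r), "flexible": simulate_ion_cloud(scene_f)}
    for mode, scene in (("rigid", scene_r), ("flexible", scene_f)):
        write_scene(traj[mode], scene, outdir, prefix=f"scene_{mode}")
    log.info("simulate: %d frames x2 in %.1f s", scene_r.n_frames, time.time() - t0)

    box = np.asarray(scene_r.box_lengths)
    spacing = float(config["grid"]["spacing"])
    grid = GridSpec.from_box(box, spacing)
    hframe = HelicalFrame.from_static_centers(
        (scene_r.cylinder_centers[0], scene_r.axis_y),
        (scene_r.cylinder_centers[1], scene_r.axis_y),
        R_DNA=scene_r.cylinder_radius,
    )
    zones = assign_zones(grid, hframe)
    helix = HelixSpec()
    shell = tuple(config["zones"]["shell"])
    zones.groove_labels = groove_mask(hframe, helix, grid, shell=shell)
    zones.save(outdir / "zones.vox.gz")

    current = "setup"
    try:
        if "density" in enabled:
            current = "density"
            t0 = time.time()
            for mode in ("rigid", "flexible"):
                field = voxel_number_density(traj[mode], "na", grid)
                field.to_csv(outdir / f"density_{mode}.csv")
                for zone in ("interface", "noninterface"):
                    for duplex in (1, 2):
                        prof = radial_profile(
                            field, hframe, zones, zone, duplex,
                            shell_width=float(config["density"]["shell_width"]),
                        )
                        prof.to_csv(
                            outdir / f"radial_{mode}_{zone}{duplex}.csv", index=False
                        )
            log.info("density: %.1f s", time.time() - t0)

        if "entropy" in enabled:
            current = "entropy"
            t0 = time.time()
            from .density import coarse_grained_density

            n_ring = int(config["entropy"]["n_ring_points"])
            r_ring = float(config["entropy"]["ring_radius"])
            rows = []
            for region, center in (
                ("ring1", hframe.mean_center(1)),
                ("ring2", hframe.mean_center(2)),
            ):
                ang = 2 * np.pi * np.arange(n_ring) / n_ring
                pts = np.stack(
                    [
                        center[0] + r_ring * np.cos(ang),
                        center[1] + r_ring * np.sin(ang),
                        np.full(n_ring, box[2] / 2.0),
                    ],
                    axis=1,
                )
                pts = np.mod(pts, box)
                series = {
                    m: coarse_grained_density(
                        traj[m], "na", pts, xi=float(config["density"]["xi"])
                    )
                    for m in ("rigid", "flexible")
                }
                res = entropy_difference(
                    series["flexible"], series["rigid"], region=region
                )
                rows.append(res.to_frame(d_separation=hframe.d))
            pd.concat(rows, ignore_index=True).to_csv(
                outdir / "entropy_report.csv", index=False
            )
            log.info("entropy: %.1f s", time.time() - t0)

        site_tables = {}
        if "diffusion" in enabled:
            current = "diffusion"
            t0 = time.time()
            dcfg = config["diffusion"]
            n_blocks = int(dcfg["n_blocks"])
            for mode in ("rigid", "flexible"):
                T = traj[mode].n_frames
                edges = np.linspace(0, T, n_blocks + 1, dtype=int)
                maps = [
                    local_diffusion_map(
                        traj[mode], "na", grid,
                        t1=float(dcfg["t1"]), t2=float(dcfg["t2"]),
                        capture_radius=float(dcfg["capture_radius"]),
                        min_events=int(dcfg["min_events"]),
                        frame_range=(int(edges[k]), int(edges[k + 1])),
                    )
                    for k in range(n_blocks)
                ]
                filt = block_consistency_filter(maps, float(dcfg["overlap_frac"]))
                keep = filt.retained & np.isfinite(filt.mean_D)
                pts = grid.points()[keep]
                sites = merge_sites(
                    pts, filt.mean_D[keep], filt.total_events[keep].astype(float),
                    min_sep=float(dcfg["min_sep"]),
                )
                sf = sites.to_frame()
                sf["zone"] = _groove_zone_of_sites(
                    sites.positions, hframe, helix, grid, zones
                )
                sf.to_csv(outdir / f"diffusion_sites_{mode}.csv", index=False)
                site_tables[mode] = sf
                rt = residence_times(
                    traj[mode], "na", sites.positions,
                    radius=float(dcfg["capture_radius"]),
                    gap_tolerance=int(dcfg["gap_tolerance"]),
                )
                rt["zone"] = sf["zone"]
                rt.to_csv(outdir / f"residence_{mode}.csv", index=False)
            log.info("diffusion: %.1f s", time.time() - t0)

        if "energetics" in enabled:
            current = "energetics"
            t0 = time.time()
            params = LJParameterSet(
                types={
                    "na": (0.0469, 1.41075),
                    "cl": (0.150, 2.27),
                    "dna": (0.10, 2.00),
                },
                pair_overrides={("na", "cl"): (0.0839, 3.23)},
            )
            tabs = {}
            for mode in ("rigid", "flexible"):
                t = traj[mode]
                types = np.empty(t.n_atoms, dtype=object)
                for g in ("dna1", "dna2"):
                    types[t.groups[g]] = "dna"
                types[t.groups["na"]] = "na"
                types[t.groups["cl"]] = "cl"
                groups = {
                    "dna1": t.groups["dna1"],
                    "dna2": t.groups["dna2"],
                    "na": t.groups["na"],
                }
                tabs[mode] = lj_decomposition(
                    t.positions[-1], types, groups, t.box, params
                )
                tabs[mode].to_csv(outdir / f"lj_{mode}.csv", index=False)
                emap, esd = voxel_energy_map(
                    t,
                    charges={"dna1": -1.0, "dna2": -1.0, "na": 1.0, "cl": -1.0},
                    grid=grid,
                    frame_stride=int(config["energetics"]["frame_stride"]),
                )
                emap.to_csv(outdir / f"voxel_energy_{mode}.csv")
            lj_difference(tabs["flexible"], tabs["rigid"]).to_csv(
                outdir / "lj_difference.csv", index=False
            )
            log.info("energetics: %.1f s", time.time() - t0)

        if "pmf" in enabled:
            current = "pmf"
            t0 = time.time()
            pcfg = config["pmf"]
            k_h, x0 = float(pcfg["k"]), float(pcfg["x0"])
            samples = force_samples_from_potential(
                lambda x: 0.5 * k_h * (x - x0) ** 2,
                (21.0, 31.0), 0.1,
                int(pcfg["samples_per_bin"]), float(pcfg["noise_sd"]),
                seed=rng_seed + 7,
            )
            windows = [
                accumulate_bins(
                    samples[(samples.d >= lo) & (samples.d < hi)], 0.1, (lo, hi)
                )
                for lo, hi in ((21.0, 24.0), (24.0, 27.0), (27.0, 31.0))
            ]
            binned = stitch_windows(windows)
            diag = convergence_diagnostics(binned)
            prof = integrate_pmf(binned, bin_se=np.nan_to_num(diag["block_se"]))
            prof.to_frame().to_csv(outdir / "pmf.csv", index=False)
            (outdir / "pmf_diagnostics.json").write_text(
                json.dumps(
                    {
                        "fraction_normal": diag["fraction_normal"],
                        "uniformity": diag["uniformity"],
                        "n_blocks": diag["n_blocks"],
                        "n_dropped": binned.n_dropped,
                    },
                    indent=2,
                )
            )
            log.info("pmf: %.1f s", time.time() - t0)

        if "stats" in enabled and site_tables:
            current = "stats"
            t0 = time.time()
            zone_values = {}
            skipped = []
            for zone in ("minor", "major", "interface"):
                va = site_tables["flexible"].query("zone == @zone")["value"].values
                vb = site_tables["rigid"].query("zone == @zone")["value"].values
                if len(va) >= 2 and len(vb) >= 2:
                    zone_values[zone] = (va, vb)
                else:
                    skipped.append(zone)
            if zone_values:
                report = zone_comparison_report(zone_values)
                report.to_csv(outdir / "effect_sizes.csv", index=False)
            if skipped:
                (outdir / "stats_skipped.json").write_text(json.dumps(skipped))
            log.info("stats: %.1f s", time.time() - t0)
    except Exception as exc:  # noqa: BLE001 - stage name context matters
        raise PipelineStageError(current, exc) from exc

    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest["files"][p.name] = _hash_file(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
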