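"""End-to-end orchestration: simulate -> segment -> quantify -> compare.

The pipeline exists so the whole quantification chain can be exercised (and
audited) on synthetic data with known ground truth: a YAML config fully
serializes a run, every stage writes standard formats (TIFF / CSV / JSON)
into the output directory, and a manifest records the config hash, package
version, and per-stage record counts. Individual stages are also invokable
through the CLI as subcommands.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, calcium, io, morphology, nuclei, stats, strain, synthetic
from .exceptions import ValidationError

log = logging.getLogger("stretchquant")

# Severity -> peak stretch ratio. The stretches correspond to Green strains of
# about 2%, 20%, 57% and 81% — the mild-to-extreme range used for membrane
# injury — with sham as the undeformed control.
SEVERITY_STRETCH = {
    "sham": 1.0,
    "mild": 1.0204,
    "moderate": 1.1824,
    "severe": 1.4616,
    "extreme": 1.6194,
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "pixel_size_um": 1.0,
    "frame_interval_s": 1.0,
    "simulate": {
        "shape": [128, 128],
        "frames": 40,
        "baseline": 100.0,
        "noise": {"poisson_gain": 0.0, "gaussian_sd": 0.4},
        "n_intact": 8,
        "n_fragment": 3,
        "wells_per_condition": 4,
        # transients planted per well, by condition (activity falls with injury)
        "conditions": {"sham": 6, "moderate": 3, "extreme": 0},
        "transient": {"amplitude": 30.0, "duration": 3, "footprint_area": 50},
        "severities": ["sham", "mild", "moderate", "severe", "extreme"],
        "puncta": {"n_spots": 25, "spot_sigma": 2.0, "amplitude": 1.0},
    },
    "segmentation": {
        "mode": "two_step",
        "min_solidity": 0.9,
        "min_area_px2": 40.0,
        "expand_distance_px": 5.0,
    },
    "aai": {"min_size_px2": 20.0, "degeneracy_floor": "auto", "threshold_scope": "frame"},
    "peaks": {"min_separation": 2},
    "strain": {
        "convention": "green",
        "rise_time_s": 0.015,
        "total_duration_s": 0.030,
        "n_points": 12,
    },
    "morphology": {"spot_scale_px": 3.0, "min_contrast": 0.0, "size_range_px2": [1.0, 200.0]},
    "stats": {"alpha": 0.05, "method": "mannwhitney", "unit": "well"},
}


def _sub_seed(seed: int, *tags: int) -> list[int]:
    return [seed & 0x7FFFFFFF, *tags]


def validate_config(config: dict) -> dict:
    return io.merge_config(DEFAULT_CONFIG, config)


def _simulate_well(cfg: dict, seed_tags: list[int], n_transients: int):
    """One simulated well: nuclei scene, somatic ROIs, calcium movie, truth."""
    sim = cfg["simulate"]
    shape = tuple(sim["shape"])
    seed = int(np.random.default_rng(seed_tags).integers(0, 2**31 - 1))
    specs = synthetic.random_nuclei_specs(
        sim["n_intact"], sim["n_fragment"], shape=shape, seed=seed
    )
    nuc_image, nuc_truth = synthetic.make_nuclei_image(
        specs, shape=shape, noise_sd=0.01, seed=seed
    )
    cell_labels = synthetic.paint_nuclei_labels(specs, shape, seed=seed)
    somata = nuclei.expand_to_soma(
        nuclei.LabelMap(cell_labels), cfg["segmentation"]["expand_distance_px"]
    )
    rng = np.random.default_rng(seed_tags + [7])
    intact_ids = [
        i + 1 for i, s in enumerate(specs) if s.shape_class == "intact_ellipse"
    ]
    tr = sim["transient"]
    transients = []
    if n_transients:
        onsets = rng.choice(
            np.arange(1, sim["frames"] - tr["duration"]),
            size=n_transients,
            replace=False,
        )
        for onset in sorted(onsets):
            transients.append(
                synthetic.TransientSpec(
                    cell_id=int(rng.choice(intact_ids)),
                    onset_frame=int(onset),
                    duration=tr["duration"],
                    footprint_area=tr["footprint_area"],
                    amplitude=tr["amplitude"],
                )
            )
    movie, movie_truth = synthetic.make_calcium_movie(
        somata.labels,
        transients,
        T=sim["frames"],
        baseline=sim["baseline"],
        noise=sim["noise"],
        seed=seed,
    )
    return nuc_image, nuc_truth, somata, movie, movie_truth


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage on a simulated experiment; return the manifest."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sim = cfg["simulate"]
    pixel = cfg["pixel_size_um"]
    manifest: dict = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "version": __version__,
        "stages": {},
    }

    # --- calcium arm: wells per condition -> AAI -> group statistics
    aai_rows = []
    for ci, (condition, n_tr) in enumerate(sorted(sim["conditions"].items())):
        for well in range(sim["wells_per_condition"]):
            nuc_image, _, somata, movie, _ = _simulate_well(
                cfg, _sub_seed(seed, 1, ci, well), n_tr
            )
            result = calcium.compute_aai(
                movie,
                min_size=cfg["aai"]["min_size_px2"],
                degeneracy_floor=cfg["aai"]["degeneracy_floor"],
                threshold_scope=cfg["aai"]["threshold_scope"],
                pixel_size=pixel,
            )
            aai_rows.append(
                {"condition": condition, "well": well, "aai": result.aai,
                 "units": result.units}
            )
            if ci == 0 and well == 0:
                io.write_stack(outdir / "example_movie.tif", movie)
                io.write_stack(outdir / "example_nuclei.tif", nuc_image)
                io.write_label_map(outdir / "example_somata.tif", somata)
    aai_table = pd.DataFrame(aai_rows)
    aai_table.to_csv(outdir / "aai_per_well.csv", index=False)
    log.info("aai: %d wells across %d conditions", len(aai_rows), len(sim["conditions"]))
    manifest["stages"]["aai"] = {"n_wells": len(aai_rows)}

    # --- nuclear segmentation demo on one scene with fragments
    specs = synthetic.random_nuclei_specs(
        sim["n_intact"], sim["n_fragment"], shape=tuple(sim["shape"]), seed=seed
    )
    image, truth = synthetic.make_nuclei_image(
        specs, shape=tuple(sim["shape"]), noise_sd=0.01, seed=seed
    )
    seg = nuclei.two_step_otsu_segment(image, mode=cfg["segmentation"]["mode"])
    filtered, records = nuclei.filter_by_solidity(
        seg,
        min_solidity=cfg["segmentation"]["min_solidity"],
        min_area=cfg["segmentation"]["min_area_px2"],
    )
    io.write_label_map(outdir / "nuclei_labels.tif", filtered)
    io.write_nucleus_records(outdir / "nuclei_records.csv", records)
    manifest["stages"]["segment_nuclei"] = {
        "n_objects": len(records),
        "n_intact": filtered.n_objects,
    }

    # --- traces and delta peak count: quiet "pre" vs active "post" recording
    _, _, somata, pre_movie, _ = _simulate_well(cfg, _sub_seed(seed, 2, 0), 1)
    _, _, _, post_movie, _ = _simulate_well(cfg, _sub_seed(seed, 2, 0), 6)
    pre_traces = calcium.extract_traces(pre_movie, somata, cfg["frame_interval_s"])
    post_traces = calcium.extract_traces(post_movie, somata, cfg["frame_interval_s"])
    delta_rows = []
    for pre_t, post_t in zip(pre_traces, post_traces):
        params = calcium.default_peak_params(pre_t.values)
        params["min_separation"] = cfg["peaks"]["min_separation"]
        res = calcium.delta_peak_count(pre_t, post_t, params)
        delta_rows.append(
            {"cell_id": res.cell_id, "pre_count": res.pre_count,
             "post_count": res.post_count, "delta": res.delta}
        )
    pd.DataFrame(delta_rows).to_csv(outdir / "delta_peak_count.csv", index=False)
    manifest["stages"]["traces"] = {"n_cells": len(delta_rows)}

    # --- strain: one simulated well per severity
    st = cfg["strain"]
    strain_rows = []
    for severity in sim["severities"]:
        spec = synthetic.DeformationSpec(
            mode="equibiaxial",
            peak_stretch=SEVERITY_STRETCH[severity],
            rise_time=st["rise_time_s"],
            total_duration=st["total_duration_s"],
            n_points=st["n_points"],
        )
        table, _ = synthetic.make_displacement_field(
            spec, dt=st["rise_time_s"] / 15, seed=seed
        )
        history = strain.strain_history_from_tracks(
            strain.tracks_from_table(table), convention=st["convention"]
        )
        strain_rows.append(
            {
                "severity": severity,
                "convention": history.convention,
                "peak_strain": history.peak_strain,
                "rise_time_s": history.rise_time,
                "peak_strain_rate_per_s": history.peak_strain_rate,
            }
        )
        if severity == "extreme":
            pd.DataFrame({"t_s": history.t, "strain": history.strain}).to_csv(
                outdir / "strain_history_extreme.csv", index=False
            )
    pd.DataFrame(strain_rows).to_csv(outdir / "strain_summary.csv", index=False)
    manifest["stages"]["strain"] = {"n_wells": len(strain_rows)}

    # --- morphology: cell-area index + puncta density on synthetic channels
    pn = sim["puncta"]
    rng = np.random.default_rng(_sub_seed(seed, 3))
    shape = tuple(sim["shape"])
    centers = [
        (float(r), float(c))
        for r, c in zip(
            rng.uniform(8, shape[0] - 8, pn["n_spots"]),
            rng.uniform(8, shape[1] - 8, pn["n_spots"]),
        )
    ]
    puncta_img, _ = synthetic.make_puncta_image(
        centers, spot_sigma=pn["spot_sigma"], amplitude=pn["amplitude"],
        noise_sd=0.02, shape=shape, seed=seed,
    )
    cai = morphology.cell_area_index(image, filtered, pixel_size=pixel)
    pres = morphology.detect_puncta(
        puncta_img,
        np.ones(shape, dtype=bool),
        spot_scale=cfg["morphology"]["spot_scale_px"],
        min_contrast=cfg["morphology"]["min_contrast"],
        size_range=tuple(cfg["morphology"]["size_range_px2"]),
        pixel_size=pixel,
    )
    pd.DataFrame(
        [
            {
                "image_id": "demo",
                "puncta_count": pres.puncta_count,
                "puncta_total_area": pres.puncta_total_area,
                "reference_area": pres.reference_area,
                "density": pres.density,
                "cell_area_index": cai.index,
            }
        ]
    ).to_csv(outdir / "morphology.csv", index=False)
    manifest["stages"]["morphology"] = {
        "puncta_count": pres.puncta_count,
        "cell_area_index": cai.index,
    }

    # --- statistics on per-well AAI across conditions
    groups = [
        stats.GroupData(cond, grp["aai"].to_numpy())
        for cond, grp in aai_table.groupby("condition", sort=True)
    ]
    comparison = stats.compare_groups(
        groups, alpha=cfg["stats"]["alpha"], method=cfg["stats"]["method"]
    )
    io.write_json(
        outdir / "stats.json",
        {
            "unit": cfg["stats"]["unit"],
            "H": comparison.H,
            "p_omnibus": comparison.p_omnibus,
            "alpha": comparison.alpha,
            "pairwise_adjusted_p": comparison.pairwise_p.tolist(),
            "group_labels": comparison.group_labels,
            "letters": comparison.letters,
        },
    )
    manifest["stages"]["stats"] = {
        "n_groups": len(groups),
        "p_omnibus": comparison.p_omnibus,
    }

    io.write_json(outdir / "manifest.json", manifest)
    return manifest
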