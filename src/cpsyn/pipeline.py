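"""Configuration and the end-to-end pipeline driver.

One master seed deterministically derives an independent stream per
stage (counter/name based), so stages can be rerun in isolation and the
whole pipeline is byte-reproducible. Each stage simulates its raw-data
type, runs the corresponding analysis, and writes delimited-text
results; a provenance manifest records the configuration hash, package
version and a SHA-256 per output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import derive_rng, derive_seed
from . import behavior, events, fourier_maps, minstim, quantification
from .synth import (
    ImagingGroundTruth,
    PsychometricObserver,
    SynapseModel,
    VWTProtocol,
    make_coloc_plan,
    simulate_minstim_cohort,
    simulate_mepsc,
    simulate_mk801,
    simulate_movie,
    simulate_ppr_pair,
    simulate_puncta_image,
    simulate_sr_release,
    simulate_vwt_session,
)
from .synth.imaging import linear_phase_field

__all__ = ["RunConfig", "run_pipeline", "read_config", "write_config"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults give a small desk-scale run."""

    seed: int = 0
    minstim: dict = field(
        default_factory=lambda: dict(
            n_cells=30, n_trials_per_vh=50, n_synapses=5, silent_fraction=0.4,
            release_prob=0.3, quantal_mean_ampa_pA=10.0, quantal_cv=0.3,
            quantal_mean_nmda_pA=10.0, noise_sd_pA=1.0,
        )
    )
    mepsc: dict = field(
        default_factory=lambda: dict(
            n_cells=4, rate_hz=5.0, duration_s=120.0, amp_mean_pA=12.0,
            amp_cv=0.3, noise_sd_pA=1.5,
        )
    )
    mk801: dict = field(
        default_factory=lambda: dict(
            n_cells=10, n_sweeps=50, n_synapses=100, release_prob=0.3,
        )
    )
    sr: dict = field(
        default_factory=lambda: dict(n_stimuli=100, window_ms=400.0)
    )
    ppr: dict = field(
        default_factory=lambda: dict(
            intervals_ms=[50.0, 100.0, 200.0], amp1_pA=80.0, depletion=0.25,
        )
    )
    maps: dict = field(
        default_factory=lambda: dict(
            shape=[64, 64], n_runs=20, n_frames=600, stim_freq_hz=0.125,
            frame_rate_hz=7.5, amplitude=2.0, od_score=0.30, noise_sd=0.2,
        )
    )
    puncta: dict = field(
        default_factory=lambda: dict(
            n_coloc=20, n_presyn_only=5, n_post_only=5, image_shape=[1688, 1688],
        )
    )
    vwt: dict = field(
        default_factory=lambda: dict(
            acuity_threshold=0.412, orientation_threshold=23.0, slope=200.0,
        )
    )
    blot: dict = field(
        default_factory=lambda: dict(
            n_blots=3, proteins=["PSD-95", "PSD-93", "GluA1"],
            samples_per_group=4, effect=1.0,
        )
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "seed" not in data:
        raise ValueError("config must set a seed")
    cfg = RunConfig(seed=int(data["seed"]))
    for name in data:
        if name == "seed":
            continue
        if not hasattr(cfg, name):
            raise ValueError(f"unknown config section {name!r}")
        section = getattr(cfg, name)
        for key, value in (data[name] or {}).items():
            if key not in section:
                raise ValueError(f"unknown key {key!r} in section {name!r}")
            section[key] = value
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    # --- minimal stimulation ------------------------------------------------
    p = dict(config.minstim)
    model = SynapseModel(
        n_synapses=p["n_synapses"], silent_fraction=p["silent_fraction"],
        release_prob=p["release_prob"],
        quantal_mean_ampa_pA=p["quantal_mean_ampa_pA"],
        quantal_cv=p["quantal_cv"],
        quantal_mean_nmda_pA=p["quantal_mean_nmda_pA"],
        noise_sd_pA=p["noise_sd_pA"], seed=derive_seed(config.seed, "minstim"),
    )
    cells = simulate_minstim_cohort(model, p["n_cells"], p["n_trials_per_vh"])
    retained, _ = minstim.qc_filter(cells)
    results = [minstim.analyze_cell(c) for c in retained]
    per_cell = minstim.summarize_cells(results)
    save(per_cell, "minstim_cells.csv")
    defined = per_cell[per_cell["estimator_defined"]]
    save(
        pd.DataFrame(
            [
                {
                    "n_cells": len(per_cell),
                    "n_estimator_defined": len(defined),
                    "mean_silent_fraction": defined["silent_fraction"].mean(),
                    "mean_potency_pA": per_cell["potency_pA"].mean(),
                    "mean_success_rate": per_cell["success_rate"].mean(),
                    "realized_silent_fraction": model.realized_silent_fraction,
                }
            ]
        ),
        "minstim_summary.csv",
    )

    # --- mEPSCs -------------------------------------------------------------
    p = dict(config.mepsc)
    series = []
    for i in range(p["n_cells"]):
        rec, _ = simulate_mepsc(
            rate_hz=p["rate_hz"], amp_mean_pA=p["amp_mean_pA"], amp_cv=p["amp_cv"],
            duration_s=p["duration_s"], noise_sd_pA=p["noise_sd_pA"],
            seed=derive_seed(config.seed, f"mepsc{i}"), cell_id=f"cell{i:03d}",
        )
        series.append(events.detect_events(rec))
    binned = events.bin_cumulative(series, "amplitude")
    save(
        pd.DataFrame(
            {"bin": np.arange(1, len(binned.bin_values) + 1),
             "amplitude_pA": binned.bin_values}
        ),
        "mepsc_amplitude_bins.csv",
    )
    save(binned.per_cell_means, "mepsc_cell_means.csv")

    # --- MK-801 -------------------------------------------------------------
    p = dict(config.mk801)
    rng = derive_rng(config.seed, "mk801")
    mk_model = SynapseModel(
        n_synapses=p["n_synapses"], silent_fraction=0.0,
        release_prob=p["release_prob"], noise_sd_pA=0.0,
        seed=derive_seed(config.seed, "mk801"),
    )
    peaks = np.vstack(
        [
            simulate_mk801(mk_model, p["n_sweeps"], rng=rng)["peak_pA"].to_numpy()
            for _ in range(p["n_cells"])
        ]
    )
    decay = events.mk801_decay(peaks)
    save(
        pd.DataFrame(
            {"sweep": np.arange(1, p["n_sweeps"] + 1),
             "normalized_peak": decay.normalized}
        ),
        "mk801_decay.csv",
    )
    save(
        pd.DataFrame(
            [{"survival": decay.survival,
              "release_prob_estimate": 1.0 - decay.survival,
              "true_release_prob": p["release_prob"]}]
        ),
        "mk801_fit.csv",
    )

    # --- Sr2+ quantal analysis ----------------------------------------------
    p = dict(config.sr)
    sr_model = SynapseModel(seed=derive_seed(config.seed, "sr"))
    ev = simulate_sr_release(sr_model, p["window_ms"], p["n_stimuli"])
    sr_res = events.sr_quantal_analysis(ev, p["window_ms"])
    save(
        pd.DataFrame(
            [{"mean_amplitude_pA": sr_res.mean_amplitude_pA,
              "mean_iei_ms": sr_res.mean_iei_ms,
              "n_events": len(sr_res.amplitudes_pA),
              "true_quantal_mean_pA": sr_model.quantal_mean_ampa_pA}]
        ),
        "sr_quantal.csv",
    )

    # --- paired-pulse ratio -------------------------------------------------
    p = dict(config.ppr)
    rows = []
    for dt in p["intervals_ms"]:
        trace = simulate_ppr_pair(p["amp1_pA"], p["depletion"], dt)
        m = events.ppr(trace, 10_000.0, 20.0, dt)
        rows.append(
            {"interval_ms": dt, "amp1_pA": m.amp1_pA, "amp2_pA": m.amp2_pA,
             "ratio": m.ratio, "true_ratio": 1.0 - p["depletion"]}
        )
    save(pd.DataFrame(rows), "ppr.csv")

    # --- imaging / ODI ------------------------------------------------------
    p = dict(config.maps)
    shape = tuple(p["shape"])
    amp = float(p["amplitude"])
    od = float(p["od_score"])
    gt = ImagingGroundTruth(
        amplitude_contra=np.full(shape, amp * (1 + od)),
        amplitude_ipsi=np.full(shape, amp * (1 - od)),
        phase=linear_phase_field(shape),
        stim_freq_hz=p["stim_freq_hz"], frame_rate_hz=p["frame_rate_hz"],
        n_frames=p["n_frames"], noise_sd=p["noise_sd"],
        seed=derive_seed(config.seed, "maps"),
    )
    rng = derive_rng(config.seed, "maps")
    run_odis = []
    for run in range(p["n_runs"]):
        contra = fourier_maps.fourier_extract(
            simulate_movie(gt, "contra", run_id=f"run{run}", rng=rng)
        )
        ipsi = fourier_maps.fourier_extract(
            simulate_movie(gt, "ipsi", run_id=f"run{run}", rng=rng)
        )
        run_odis.append(fourier_maps.od_analysis(contra, ipsi).odi)
    block = fourier_maps.odi_blocks(run_odis)
    scatter = fourier_maps.map_scatter(contra)
    save(
        pd.DataFrame(
            {"run": np.arange(len(run_odis)), "odi": run_odis}
        ),
        "odi_runs.csv",
    )
    save(
        pd.DataFrame(
            [{"animal_odi": np.nan if block.excluded else block.animal_odi,
              "n_blocks": len(block.block_odis), "excluded": block.excluded,
              "map_scatter_rad": scatter, "programmed_od_score": od}]
        ),
        "odi_summary.csv",
    )

    # --- puncta -------------------------------------------------------------
    p = dict(config.puncta)
    plan = make_coloc_plan(p["n_coloc"], p["n_presyn_only"], p["n_post_only"])
    img, truth = simulate_puncta_image(
        plan, image_shape=tuple(p["image_shape"]),
        seed=derive_seed(config.seed, "puncta"),
    )
    munc = quantification.segment_puncta(img[0], "munc13")
    psd = quantification.segment_puncta(img[1], "psd95")
    pairs = quantification.colocalize(munc, psd)
    density = quantification.synapse_density(
        len(pairs), munc.image_area_um2, munc.section_thickness_nm
    )
    save(pairs, "puncta_pairs.csv")
    save(
        pd.DataFrame(
            [{"n_munc13": len(munc), "n_psd95": len(psd), "n_synapses": len(pairs),
              "density_per_um3": density,
              "planned_synapses": int(
                  (truth["has_munc13"] & truth["has_psd95"]).sum())}]
        ),
        "puncta_summary.csv",
    )

    # --- visual water task --------------------------------------------------
    p = dict(config.vwt)
    rows = []
    for task, tau, proto in (
        ("acuity", p["acuity_threshold"], VWTProtocol.acuity()),
        ("orientation", p["orientation_threshold"], VWTProtocol.orientation()),
    ):
        obs = PsychometricObserver(
            task=task, true_threshold=tau, slope=p["slope"],
            seed=derive_seed(config.seed, f"vwt-{task}"),
        )
        log = simulate_vwt_session(obs, proto)
        thr = (
            behavior.acuity_threshold(log)
            if task == "acuity"
            else behavior.orientation_threshold(log)
        )
        rows.append(
            {"task": task, "threshold": thr, "true_threshold": tau,
             "blocks_to_learn": behavior.blocks_to_learn(log)}
        )
    save(pd.DataFrame(rows), "vwt.csv")

    # --- western blots ------------------------------------------------------
    p = dict(config.blot)
    rng = derive_rng(config.seed, "blot")
    rows = []
    for blot in range(p["n_blots"]):
        gain = rng.uniform(0.5, 2.0)  # per-blot detection gain
        for protein in p["proteins"]:
            for group, mult in (("control", 1.0), ("treatment", p["effect"])):
                for s in range(p["samples_per_group"]):
                    rows.append(
                        {"protein": protein,
                         "sample_id": f"{group[0]}{s}",
                         "group": group,
                         "band_intensity": gain * mult * rng.lognormal(0.0, 0.15),
                         "blot_id": f"blot{blot}"}
                    )
    blot_table = pd.DataFrame(rows)
    normalized, _ = quantification.normalize_blot(blot_table, "control")
    save(normalized, "blot_relative.csv")

    manifest = {
        "tool": "cpsyn",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {path.name: _sha256(path) for path in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
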