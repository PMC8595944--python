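"""End-to-end pipeline orchestration with file-based stage hand-off.

Stages (``synth -> preprocess -> features -> network -> report``) exchange
data exclusively through files in the run directory, so any stage can be
re-run in isolation::

    run/
      cohort.csv              synthesized cohort table
      eeg/<id>.edf            raw synthetic recordings
      clean/<id>.edf          re-referenced + filtered recordings
      masks/<id>.json         kept/rejected epochs with reasons
      features.csv            per-subject feature table (+ exclusions.csv)
      spectra/<group>.csv     group-median PSDn curves
      networks/               matrices (CSV), networks (JSON + GraphML)
      report/                 Markdown + CSV cohort comparison
      manifest.json           config hash, seed, versions, per-stage counts

Everything is deterministic under a fixed master seed: per-(measure, group)
bootstrap seeds are derived through ``numpy.random.SeedSequence`` with fixed
keys, so adding a group does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import network as net_mod
from . import preprocess as pre_mod
from . import report as report_mod
from .recording import read_edf, write_edf
from .spectral import build_feature_table, epoch_psd, find_spectral_peak, group_median_spectrum
from .synthetic import (
    GROUP_LABELS,
    REALISTIC_CORRELATION,
    CohortSynthesisSpec,
    synthesize_cohort,
    synthesize_eeg,
)

ALL_STAGES = ("synth", "preprocess", "features", "network", "report")
MEASURES = ("rp", "specen")


@dataclasses.dataclass
class SynthConfig:
    group_sizes: tuple[int, int, int] = (176, 98, 20)
    duration_s: float = 600.0
    n_channels: int = 8
    artifact_rate: float = 0.0
    latent_structure: str = "realistic"  # "realistic" or "null"


@dataclasses.dataclass
class PreprocessConfig:
    epoch_length_s: float = 30.0
    k_amp: float = 5.0
    k_pow: float = 10.0
    trim_minutes: float = 5.0
    notch_hz: float = 60.0
    band_hz: tuple[float, float] = (0.1, 70.0)


@dataclasses.dataclass
class NetworkConfig:
    n_boot: int = 1000
    n_subsample: int = 20
    threshold: float = 0.30
    layout_iterations: int = 500


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _build_dataclass(cls, mapping: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} under '{path}'"
        )
    kwargs: dict[str, Any] = {}
    for name, value in mapping.items():
        field_type = fields[name].type
        if isinstance(value, dict) and name in ("synth", "preprocess", "network"):
            sub_cls = {"synth": SynthConfig, "preprocess": PreprocessConfig,
                       "network": NetworkConfig}[name]
            kwargs[name] = _build_dataclass(sub_cls, value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
        del field_type
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config, rejecting unknown keys by name."""
    mapping = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(mapping)


def config_from_dict(mapping: dict) -> RunConfig:
    return _build_dataclass(RunConfig, mapping, "run")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_synth(config: RunConfig, run_dir: Path) -> dict:
    latent = REALISTIC_CORRELATION if config.synth.latent_structure == "realistic" else None
    cohort = synthesize_cohort(
        CohortSynthesisSpec(
            group_sizes=tuple(config.synth.group_sizes),
            eeg_duration=config.synth.duration_s,
            eeg_channels=config.synth.n_channels,
            artifact_rate=config.synth.artifact_rate,
            latent_correlation=latent,
            seed=config.seed,
        )
    )
    cohort.table.to_csv(run_dir / "cohort.csv", index=False)
    eeg_dir = run_dir / "eeg"
    eeg_dir.mkdir(exist_ok=True)
    for sid, spec in cohort.eeg_specs.items():
        rec = synthesize_eeg(spec)
        rec.subject_id = sid
        write_edf(rec, eeg_dir / f"{sid}.edf")
    return {"subjects": len(cohort.table)}


def stage_preprocess(config: RunConfig, run_dir: Path) -> dict:
    eeg_dir = run_dir / "eeg"
    clean_dir = run_dir / "clean"
    mask_dir = run_dir / "masks"
    clean_dir.mkdir(exist_ok=True)
    mask_dir.mkdir(exist_ok=True)
    pc = config.preprocess
    n_files, n_kept, n_total = 0, 0, 0
    for edf in sorted(eeg_dir.glob("*.edf")):
        rec = read_edf(edf)
        rec = pre_mod.rereference_common_average(rec)
        rec = pre_mod.filter_eeg(rec, band_hz=tuple(pc.band_hz), notch_hz=pc.notch_hz)
        epoch_length = int(round(pc.epoch_length_s * rec.sampling_rate))
        mask = pre_mod.reject_artifacts(
            rec, epoch_length=epoch_length, k_amp=pc.k_amp, k_pow=pc.k_pow
        )
        mask = pre_mod.trim_edges(rec, mask, trim_minutes=pc.trim_minutes)
        write_edf(rec, clean_dir / edf.name)
        mask.to_json(mask_dir / f"{edf.stem}.json", subject_id=edf.stem)
        n_files += 1
        n_kept += mask.n_kept
        n_total += mask.n_epochs
    return {"recordings": n_files, "epochs_kept": n_kept, "epochs_total": n_total}


def stage_features(config: RunConfig, run_dir: Path) -> dict:
    cohort = pd.read_csv(run_dir / "cohort.csv")
    clean_dir = run_dir / "clean"
    mask_dir = run_dir / "masks"
    spectra = {}
    for edf in sorted(clean_dir.glob("*.edf")):
        mask_path = mask_dir / f"{edf.stem}.json"
        mask = pre_mod.EpochMask.from_json(mask_path) if mask_path.exists() else None
        rec = read_edf(edf)
        spectra[edf.stem] = epoch_psd(rec, mask=mask)
    table, exclusions = build_feature_table(cohort, spectra)
    table.to_csv(run_dir / "features.csv", index=False)
    exclusions.to_csv(run_dir / "exclusions.csv", index=False)

    spectra_dir = run_dir / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    groups = dict(zip(cohort["id"].astype(str), cohort["group"]))
    medians = group_median_spectrum(spectra.values(), groups)
    peaks = {}
    for label, frame in medians.items():
        frame.to_csv(spectra_dir / f"{label}.csv", index=False)
        peak = find_spectral_peak(
            frame["frequency"].to_numpy(), frame["median"].to_numpy(), (0.2, 1.0)
        )
        peaks[label] = {
            "frequency_hz": peak.frequency,
            "amplitude": peak.amplitude,
            "at_boundary": peak.at_boundary,
        }
    (spectra_dir / "so_peaks.json").write_text(json.dumps(peaks, indent=1))
    return {"subjects": len(table), "excluded": len(exclusions)}


def stage_network(config: RunConfig, run_dir: Path) -> dict:
    table = pd.read_csv(run_dir / "features.csv")
    net_dir = run_dir / "networks"
    net_dir.mkdir(exist_ok=True)
    nc = config.network
    built = 0
    for m_idx, measure in enumerate(MEASURES):
        for g_idx, group in enumerate(GROUP_LABELS):
            if (table["group"] == group).sum() < 2:
                continue
            sub_seed = int(
                np.random.SeedSequence([config.seed, m_idx, g_idx]).generate_state(1)[0]
                % (2**31)
            )
            mat = net_mod.bootstrap_matrix(
                table, group, measure,
                n_boot=nc.n_boot, n_subsample=nc.n_subsample, seed=sub_seed,
            )
            stem = f"{measure}_{group}"
            mat.to_csv(net_dir, stem)
            net = net_mod.threshold_network(mat, threshold=nc.threshold)
            net_mod.layout_fruchterman_reingold(
                net, iterations=nc.layout_iterations, seed=sub_seed
            )
            net_mod.modularity_partition(net)
            net_mod.centrality_measures(net)
            net_mod.network_to_json(net, net_dir / f"{stem}.json")
            net_mod.network_to_graphml(net, net_dir / f"{stem}.graphml")
            radar = net_mod.radar_summary(mat)
            radar.band_vs_variable.to_csv(net_dir / f"{stem}_radar.csv")
            built += 1
    return {"networks": built}


def stage_report(config: RunConfig, run_dir: Path) -> dict:
    table = pd.read_csv(run_dir / "features.csv")
    comparisons = report_mod.compare_groups(table)
    report_mod.write_report(comparisons, run_dir / "report")
    return {"variables": len(comparisons)}


STAGE_FUNCS = {
    "synth": stage_synth,
    "preprocess": stage_preprocess,
    "features": stage_features,
    "network": stage_network,
    "report": stage_report,
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns (and writes) the manifest.

    Inputs are checked before any stage runs.  On stage failure the partial
    outputs are preserved and the manifest records the failure point.
    """
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stage_inputs = {
        "synth": (),
        "preprocess": ("eeg",),
        "features": ("cohort.csv", "clean", "masks"),
        "network": ("features.csv",),
        "report": ("features.csv",),
    }
    first = next((s for s in ALL_STAGES if s in config.stages), None)
    if first is not None:
        for name in stage_inputs[first]:
            if not (run_dir / name).exists():
                raise FileNotFoundError(
                    f"missing input {run_dir / name}; "
                    "run the earlier stages or enable 'synth'"
                )
    config.to_yaml(run_dir / "config.yaml")

    import scipy

    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "somnospec": _package_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "status": "ok",
    }
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            manifest["stages"][stage] = STAGE_FUNCS[stage](config, run_dir)
    except Exception as exc:
        manifest["status"] = f"failed at {stage}: {exc}"
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _package_version() -> str:
    from . import __version__

    return __version__
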