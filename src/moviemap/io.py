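"""Bundle I/O, configuration, and reproducible pipeline orchestration.

A :class:`~moviemap.simulate.StudyBundle` is written as a small file set:
an HDF5 container (recordings, sheet arrays, maps, lines), a JSON sidecar
(config, seeds, package version, and a checksum over the config so silent
edits are detected on read), and TSV tables (per-unit labels and gradient
lines) for interoperability. Per-unit scalar maps can be exported to GIFTI.

``run_pipeline`` executes simulate -> homotopy -> ica -> srm stages from a
TOML or YAML config (schema-checked with pydantic before any compute) and
writes a JSON report containing every statistic and every seed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .sheet import GroundTruthMaps, build_cortical_sheet, trace_gradient_lines
from .simulate import (
    ParticipantRecording,
    SimulationConfig,
    StudyBundle,
    simulate_cohort,
)
from .stats import ContractError

__all__ = [
    "write_bundle",
    "read_bundle",
    "ProvenanceWarning",
    "BundleVersionError",
    "export_map_gifti",
    "import_map_gifti",
    "PipelineConfig",
    "run_pipeline",
]

BUNDLE_FORMAT_VERSION = 1


class ProvenanceWarning(UserWarning):
    """The sidecar's stored config hash does not match its config."""


class BundleVersionError(RuntimeError):
    """The on-disk bundle format is incompatible with this package version."""


def _config_digest(config_dict: dict) -> str:
    payload = json.dumps(config_dict, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def write_bundle(bundle: StudyBundle, path: str | Path) -> Path:
    """Write a bundle as ``bundle.h5`` + ``bundle.json`` + TSV tables.

    ``path`` is a directory (created if absent). Returns the directory.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sheet = bundle.sheet
    with h5py.File(path / "bundle.h5", "w") as f:
        f.attrs["format_version"] = BUNDLE_FORMAT_VERSION
        g = f.create_group("sheet")
        g.attrs["height"] = sheet.height
        g.attrs["width"] = sheet.width
        g.attrs["scheme"] = sheet.scheme
        g = f.create_group("maps")
        g.create_dataset("spatial_frequency", data=bundle.maps.spatial_frequency)
        g.create_dataset("meridian", data=bundle.maps.meridian)
        for i, rec in enumerate(bundle.recordings):
            g = f.create_group(f"recordings/p{i:03d}")
            g.create_dataset("data", data=rec.data)
            g.create_dataset("motion", data=rec.motion)
            g.create_dataset("loadings", data=rec.loadings)
            g.create_dataset("map_spatial_frequency", data=rec.maps.spatial_frequency)
            g.create_dataset("map_meridian", data=rec.maps.meridian)
            g.attrs["tr"] = rec.tr
            g.attrs["seed"] = rec.seed
            g.attrs["participant"] = rec.participant
            g.create_dataset("movie_intervals", data=np.asarray(rec.movie_intervals))
    config_dict = bundle.config.to_dict()
    sidecar = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "package_version": __version__,
        "config": config_dict,
        "config_sha256": _config_digest(config_dict),
        "n_participants": bundle.n_participants,
    }
    (path / "bundle.json").write_text(json.dumps(sidecar, indent=2))
    unit_table = pd.DataFrame(
        {
            "hemi": sheet.hemi,
            "row": sheet.row,
            "col": sheet.col,
            "area": sheet.area,
            "stream": sheet.stream,
            "level": sheet.level,
            "eccentricity": sheet.eccentricity,
            "polar_angle": sheet.polar_angle,
        }
    )
    unit_table.to_csv(path / "units.tsv", sep="\t", index_label="unit")
    lines_rows = []
    for kind, lines in (
        ("parallel", bundle.lines_parallel),
        ("perpendicular", bundle.lines_perpendicular),
    ):
        for i, ln in enumerate(lines):
            lines_rows.append(
                {
                    "orientation": kind,
                    "line": i,
                    "hemi": ln.hemi,
                    "areas": "|".join(ln.areas),
                    "indices": ",".join(map(str, ln.indices)),
                }
            )
    pd.DataFrame(lines_rows).to_csv(path / "lines.tsv", sep="\t", index=False)
    return path


def read_bundle(path: str | Path) -> StudyBundle:
    """Read a bundle written by :func:`write_bundle`.

    Raises :class:`BundleVersionError` on a format mismatch and emits a
    :class:`ProvenanceWarning` when the sidecar's config hash does not match
    its stored config.
    """
    path = Path(path)
    sidecar = json.loads((path / "bundle.json").read_text())
    if sidecar.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise BundleVersionError(
            f"bundle format {sidecar.get('format_version')} is not supported"
        )
    if _config_digest(sidecar["config"]) != sidecar.get("config_sha256"):
        warnings.warn(
            "bundle sidecar config does not match its stored checksum; "
            "provenance cannot be trusted",
            ProvenanceWarning,
            stacklevel=2,
        )
    config = SimulationConfig(**sidecar["config"])
    with h5py.File(path / "bundle.h5", "r") as f:
        sheet = build_cortical_sheet(
            int(f["sheet"].attrs["height"]),
            int(f["sheet"].attrs["width"]),
            str(f["sheet"].attrs["scheme"]),
        )
        maps = GroundTruthMaps(
            spatial_frequency=f["maps/spatial_frequency"][()],
            meridian=f["maps/meridian"][()],
        )
        recordings = []
        for name in sorted(f["recordings"]):
            g = f[f"recordings/{name}"]
            recordings.append(
                ParticipantRecording(
                    data=g["data"][()],
                    tr=float(g.attrs["tr"]),
                    movie_intervals=tuple(
                        (int(s), int(e)) for s, e in g["movie_intervals"][()]
                    ),
                    motion=g["motion"][()],
                    seed=int(g.attrs["seed"]),
                    participant=int(g.attrs["participant"]),
                    loadings=g["loadings"][()],
                    maps=GroundTruthMaps(
                        spatial_frequency=g["map_spatial_frequency"][()],
                        meridian=g["map_meridian"][()],
                    ),
                )
            )
    return StudyBundle(
        sheet=sheet,
        maps=maps,
        lines_parallel=trace_gradient_lines(sheet, "parallel"),
        lines_perpendicular=trace_gradient_lines(sheet, "perpendicular"),
        recordings=recordings,
        config=config,
        provenance=sidecar,
    )


def export_map_gifti(values: np.ndarray, path: str | Path) -> Path:
    """Write a per-unit scalar map as a GIFTI functional file."""
    import nibabel as nib

    darray = nib.gifti.GiftiDataArray(
        np.asarray(values, dtype=np.float32), intent="NIFTI_INTENT_NONE"
    )
    img = nib.gifti.GiftiImage(darrays=[darray])
    path = Path(path)
    nib.save(img, str(path))
    return path


def import_map_gifti(path: str | Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float)


class HomotopyStageConfig(BaseModel):
    enabled: bool = True
    control_motion: bool = False
    run_mds: bool = False
    n_boot: int = Field(default=10_000, ge=1)


class ICAStageConfig(BaseModel):
    enabled: bool = False
    n_components: int | str = "auto"
    participant: int = 0


class SRMStageConfig(BaseModel):
    enabled: bool = False
    k: int = Field(default=10, ge=1)
    n_boot: int = Field(default=10_000, ge=1)
    test_participants: list[int] | None = None


class PipelineConfig(BaseModel):
    """Schema-checked configuration for ``run_pipeline``."""

    simulate: dict = Field(default_factory=dict)
    homotopy: HomotopyStageConfig = Field(default_factory=HomotopyStageConfig)
    ica: ICAStageConfig = Field(default_factory=ICAStageConfig)
    srm: SRMStageConfig = Field(default_factory=SRMStageConfig)
    seed: int = 0
    out: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(text)
        else:
            raw = yaml.safe_load(text)
        try:
            return cls(**(raw or {}))
        except ValidationError as err:
            raise ContractError(f"invalid pipeline config: {err}") from err


class PipelineConfigError(ValueError):
    """The pipeline configuration is inconsistent with the simulated data."""


def run_pipeline(config: PipelineConfig | str | Path, out: str | Path | None = None) -> dict:
    """Execute the requested stages and return (and optionally write) a report.

    All validation that can fail runs before any compute (e.g. an SRM ``k``
    larger than the movie length is rejected up front). The report contains
    every statistic and every seed; identical configs produce identical
    statistical sections.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    sim_config = SimulationConfig(**config.simulate)
    t_movie = sim_config.n_timepoints - sim_config.hemodynamic_shift_trs
    if config.srm.enabled and config.srm.k > t_movie:
        raise PipelineConfigError(
            f"srm.k = {config.srm.k} exceeds the movie length {t_movie}"
        )
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            "simulate": sim_config.to_dict(),
            "homotopy": config.homotopy.model_dump(),
            "ica": config.ica.model_dump(),
            "srm": config.srm.model_dump(),
        },
    }
    bundle = simulate_cohort(sim_config)
    if config.homotopy.enabled:
        from .homotopy import HomotopyAnalysis

        res = HomotopyAnalysis(
            bundle,
            control_motion=config.homotopy.control_motion,
            run_mds=config.homotopy.run_mds,
        ).fit(n_boot=config.homotopy.n_boot, seed=config.seed)
        report["homotopy"] = {
            "group_means_r": res.group_means_r().to_dict(),
            "tests": {k: v.to_dict() for k, v in res.tests.items()},
        }
        if res.embedding is not None:
            report["homotopy"]["mds_stress"] = res.embedding.stress
            report["homotopy"]["stream_silhouette"] = res.stream_silhouette
    if config.ica.enabled:
        from .ica import SpatialICA

        res = SpatialICA(
            bundle.recordings[config.ica.participant],
            bundle.sheet,
            bundle.lines_parallel,
            bundle.lines_perpendicular,
            n_components=config.ica.n_components,
        ).fit(seed=config.seed)
        report["ica"] = {
            "n_components": res.components.n_components,
            "converged": res.components.converged,
            "evaluation": res.evaluation.to_dict(orient="records"),
        }
    if config.srm.enabled:
        from .srm import leave_one_out_experiment

        res = leave_one_out_experiment(
            bundle,
            k=config.srm.k,
            n_boot=config.srm.n_boot,
            seed=config.seed,
            test_participants=config.srm.test_participants,
        )
        report["srm"] = {
            "k": res.k,
            "mean_corr": {
                mt: {
                    col: res.mean_corr(mt, col)
                    for col in ("corr_real", "corr_flipped", "corr_anatomical")
                }
                for mt in res.table["map_type"].unique()
            },
            "tests": {k: v.to_dict() for k, v in res.tests.items()},
        }
    out = out or config.out
    if out is not None:
        Path(out).parent.mkdir(parents=True, exist_ok=True)
        Path(out).write_text(json.dumps(report, indent=2, default=float))
    return report
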