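"""End-to-end pipeline: segment → histogram → fit → classify →
probability map → biopsy targets, with a manifest for reproducibility.

Each stage's output is persisted under the output directory together
with the configuration (echoed verbatim) and a run manifest holding the
tool version, config hash, input checksums, seeds and timestamps. A
stage failure halts the run with a stage-named error before later
outputs are written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .exceptions import AdchistError, ValidationError
from .mixture import (
    DEFAULT_BINS,
    DEFAULT_RANGE,
    DEFAULT_THRESHOLD,
    build_histogram,
    classify_phenotype,
    fit_double_gaussian,
)
from .probmap import TARGET_EDGE_MM, make_probability_map, select_targets
from .segmentation import t1_subtraction_mask
from .volumes import read_adc, read_anatomical, read_mask, write_volume

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a single-subject run; serializable to YAML/JSON."""

    adc_path: str
    pre_t1_path: str
    post_t1_path: str
    out_dir: str
    brain_mask_path: str | None = None
    exclusion_mask_path: str | None = None
    adc_unit: str | None = None
    threshold: float = DEFAULT_THRESHOLD
    n_bins: int = DEFAULT_BINS
    hist_range: tuple[float, float] = DEFAULT_RANGE
    n_starts: int = 8
    seed: int = 0
    n_target_pairs: int = 1
    target_edge_mm: float = TARGET_EDGE_MM
    min_component_voxels: int = 10

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValidationError("n_bins must be >= 8")
        if self.n_starts < 1:
            raise ValidationError("n_starts must be >= 1")
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        if self.target_edge_mm <= 0:
            raise ValidationError("target_edge_mm must be positive")
        self.hist_range = tuple(float(v) for v in self.hist_range)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_checksums: dict
    seed: int
    started: str
    finished: str = ""
    stages: list = field(default_factory=list)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages for one subject; returns the result bundle.

    Outputs written to ``config.out_dir``: the echoed config, the
    enhancement mask and probability map (NIfTI), histogram CSV, fit
    and phenotype and targets JSON, and the run manifest.
    """
    out = Path(config.out_dir)

    for label, p in (("ADC", config.adc_path), ("pre-contrast T1", config.pre_t1_path),
                     ("post-contrast T1", config.post_t1_path)):
        if not Path(p).exists():
            raise ValidationError(f"stage 'load': missing {label} file {p}")

    out.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    checksums = {
        Path(p).name: _sha256(p)
        for p in (config.adc_path, config.pre_t1_path, config.post_t1_path)
    }
    manifest = RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        input_checksums=checksums,
        seed=config.seed,
        started=datetime.now(timezone.utc).isoformat(),
    )

    def stage(name, fn):
        log.info("stage=%s seed=%d", name, config.seed)
        try:
            result = fn()
        except AdchistError as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc
        manifest.stages.append(name)
        return result

    adc = stage("load", lambda: read_adc(config.adc_path, unit=config.adc_unit))
    pre = read_anatomical(config.pre_t1_path)
    post = read_anatomical(config.post_t1_path)
    brain = (
        read_mask(config.brain_mask_path)
        if config.brain_mask_path
        else np.ones(adc.shape, dtype=bool)
    )
    exclusion = read_mask(config.exclusion_mask_path) if config.exclusion_mask_path else None

    roi = stage("segment", lambda: t1_subtraction_mask(pre, post, brain, config.min_component_voxels))
    write_volume(roi.mask.astype(np.uint8), out / "enhancement_mask.nii.gz", affine=post.affine)

    hist = stage("histogram", lambda: build_histogram(adc, roi, config.n_bins, config.hist_range))
    np.savetxt(
        out / "histogram.csv",
        np.column_stack([hist.centers, hist.density]),
        delimiter=",",
        header="bin_center_um2_per_ms,density",
        comments="",
    )

    fit = stage("fit", lambda: fit_double_gaussian(hist, n_starts=config.n_starts, seed=config.seed))
    with open(out / "fit.json", "w") as fh:
        json.dump(
            {**dataclasses.asdict(fit), "n_bins": config.n_bins, "hist_range": list(config.hist_range),
             "n_voxels": hist.n_voxels, "seed": config.seed},
            fh, indent=2,
        )

    call = stage("classify", lambda: classify_phenotype(fit, config.threshold))
    with open(out / "phenotype.json", "w") as fh:
        json.dump(dataclasses.asdict(call), fh, indent=2)

    pmap = stage("probmap", lambda: make_probability_map(adc, roi, fit))
    write_volume(pmap.values, out / "probability_map.nii.gz", affine=adc.affine)

    targets = stage(
        "targets",
        lambda: select_targets(pmap, exclusion, config.n_target_pairs, config.target_edge_mm),
    )
    with open(out / "targets.json", "w") as fh:
        json.dump([dataclasses.asdict(t) for t in targets], fh, indent=2)

    manifest.finished = datetime.now(timezone.utc).isoformat()
    with open(out / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)

    return {"roi": roi, "histogram": hist, "fit": fit, "phenotype": call,
            "probability_map": pmap, "targets": targets, "manifest": manifest}
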