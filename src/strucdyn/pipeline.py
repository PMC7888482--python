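"""End-to-end study orchestration: simulate/load -> preprocess -> featurize ->
associate -> report.

The pipeline is thin: every number in a :class:`StudyReport` is reproducible
call-for-call from the library operations.  All randomness flows from the
single seed in the study config through the generator's named substreams.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import StrengthDynamicsModel, StrengthDynamicsResults
from .features import DEFAULT_FEATURES, FEATURE_REGISTRY
from .io import load_study, read_adjacency_tsv, read_bold_tsv, read_region_table, write_study
from .preprocess import PreprocessConfig
from .synthetic import SyntheticStudyConfig, generate_study

__all__ = ["StudyConfig", "StudyReport", "run_study", "validate_inputs"]


@dataclass
class StudyConfig:
    """Configuration of a full analysis run (YAML-serializable).

    Either ``simulate`` holds a :class:`SyntheticStudyConfig` or
    ``study_dir`` points at an on-disk study directory.
    """

    simulate: SyntheticStudyConfig | None = None
    study_dir: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: list[str] = field(default_factory=lambda: list(DEFAULT_FEATURES))
    q: float = 0.05
    primary_feature: str = "rlfp"
    out_dir: str | None = None
    write_inputs: bool = False

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.study_dir is None):
            raise ValueError("specify exactly one of 'simulate' or 'study_dir'")
        unknown = [f for f in self.features if f not in FEATURE_REGISTRY]
        if unknown:
            raise ValueError(f"unknown features in config: {unknown}")
        if self.primary_feature not in self.features:
            raise ValueError("primary_feature must be among the requested features")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.pop("simulate", None)
        pre = raw.pop("preprocess", None)
        return cls(
            simulate=SyntheticStudyConfig(**sim) if sim else None,
            preprocess=PreprocessConfig(**pre) if pre else PreprocessConfig(),
            **raw,
        )


@dataclass
class StudyReport:
    """Results plus provenance for one end-to-end run."""

    results: StrengthDynamicsResults
    config_hash: str
    seed: int | None
    version: str

    def summary(self) -> str:
        head = (
            f"strucdyn {self.version} | config {self.config_hash[:12]} | "
            f"seed {self.seed}"
        )
        return head + "\n" + self.results.summary()

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.group.to_csv(out / "group_associations.tsv", sep="\t")
        self.results.ranking.to_csv(out / "feature_ranking.tsv", sep="\t")
        for name, sweep in self.results.sweeps.items():
            sweep.table.to_csv(out / f"individual_{name}.tsv", sep="\t")
        (out / "report.txt").write_text(self.summary() + "\n")
        return out


def _config_hash(config: StudyConfig) -> str:
    from dataclasses import asdict

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError

    payload = yaml.safe_dump(
        {
            "simulate": asdict(config.simulate) if config.simulate else None,
            "study_dir": config.study_dir,
            "features": config.features,
            "q": config.q,
            "highpass_hz": config.preprocess.highpass_hz,
            "detrend": config.preprocess.detrend,
            "zscore": config.preprocess.zscore,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def run_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline for one study configuration.

    Stages run in fixed order (simulate/load, preprocess, featurize,
    associate); a failure in any stage aborts with the stage name attached.
    Deterministic given the config seed.
    """
    stage = "simulate/load"
    try:
        if config.simulate is not None:
            study = generate_study(config.simulate)
            if config.out_dir and config.write_inputs:
                write_study(study, Path(config.out_dir) / "study")
        else:
            study = load_study(config.study_dir)

        stage = "preprocess+featurize"
        model = StrengthDynamicsModel.from_study(
            study, feature_names=config.features, preprocess_config=config.preprocess
        )

        stage = "associate"
        results = model.fit(q=config.q)
    except Exception as exc:
        raise RuntimeError(f"study failed in stage '{stage}': {exc}") from exc

    report = StudyReport(
        results=results,
        config_hash=_config_hash(config),
        seed=config.simulate.seed if config.simulate else None,
        version=__version__,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def validate_inputs(paths: dict) -> list[tuple[str, str]]:
    """Validate user-supplied study files without raising.

    ``paths`` may contain ``bold`` (list of files), ``connectomes`` (list of
    files) and ``regions`` (one file).  Returns (level, message) pairs,
    level in {"fatal", "warning", "ok"}.
    """
    findings: list[tuple[str, str]] = []
    n_regions = None
    for p in paths.get("bold", []):
        try:
            bold = read_bold_tsv(p)
        except Exception as exc:
            findings.append(("fatal", f"{p}: {exc}"))
            continue
        if n_regions is None:
            n_regions = bold.n_regions
        elif bold.n_regions != n_regions:
            findings.append(("fatal", f"{p}: region count {bold.n_regions} != {n_regions}"))
        findings.append(("ok", f"{p}: {bold.n_regions} regions x {bold.n_timepoints} @ tr={bold.tr}"))
    for p in paths.get("connectomes", []):
        try:
            conn = read_adjacency_tsv(p)
        except Exception as exc:
            findings.append(("fatal", f"{p}: {exc}"))
            continue
        if n_regions is not None and conn.n_regions != n_regions:
            findings.append(("fatal", f"{p}: adjacency size {conn.n_regions} != {n_regions}"))
        else:
            findings.append(("ok", f"{p}: {conn.n_regions} x {conn.n_regions} adjacency"))
    if "regions" in paths:
        try:
            table = read_region_table(paths["regions"])
            if (table["volume_voxels"] <= 0).any():
                findings.append(
                    ("warning", "region table contains non-positive volumes "
                                "(volume is used as a rank covariate)")
                )
            else:
                findings.append(("ok", f"region table: {len(table)} regions"))
        except Exception as exc:
            findings.append(("fatal", f"{paths['regions']}: {exc}"))
    return findings
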