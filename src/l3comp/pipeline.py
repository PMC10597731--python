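"""End-to-end orchestration: read -> QC -> segment -> measure -> statistics.

`run_pipeline` consumes a slice manifest (one row per DICOM file with
patient metadata and the mid-L3 designation) and emits five artifacts
into the output directory:

* ``measures.csv``      — tidy per-slice, per-tissue area and radiodensity;
* ``variability.csv``   — per-patient average percent differences;
* ``table1.csv``        — mid-L3 measures by sex: median (IQR) + Mann-Whitney p;
* ``table2.csv``        — average percent differences by sex, same schema;
* ``qc_report.csv``     — per-patient QC flags and whether the patient
  entered the statistics (excluded patients are listed, never dropped
  silently).

Outputs are deterministic: rerunning on unchanged inputs reproduces the
CSV files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dicom_io import (
    DEFAULT_ARTEFACT_BOUND_HU,
    DEFAULT_NOISE_SD_HU,
    load_study,
    qc_study,
)
from .errors import ConfigError, InsufficientDataError, L3CompError
from .metrics import measure_slice, measures_to_frame
from .segmentation import (
    ALBERTA,
    DEFAULT_MORPHOLOGY,
    MorphologyParams,
    ThresholdSet,
    segment_composition,
)
from .variability import (
    CohortSummary,
    build_variability_records,
    compare_groups,
    sex_comparison,
    summaries_to_frame,
)

logger = logging.getLogger("l3comp")

#: CSV float format shared by all outputs (fixed for byte-reproducibility).
CSV_FLOAT_FORMAT = "%.6g"

_MID_MEASURE_COLS = {"area": "area_cm2", "radiodensity": "radiodensity_hu"}


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, in one serialisable object."""

    manifest: str
    output_dir: str
    thresholds: ThresholdSet = field(default_factory=ThresholdSet)
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    qc_noise_sd_hu: float = DEFAULT_NOISE_SD_HU
    qc_artefact_bound_hu: float = DEFAULT_ARTEFACT_BOUND_HU
    stats_mode: str = "auto"  # exact | asymptotic | auto
    alpha: float = 0.05
    seed: int = 0
    include_flagged: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"significance level must lie in (0, 1), got {self.alpha}")
        if self.stats_mode not in ("exact", "asymptotic", "auto"):
            raise ConfigError(f"unknown stats mode {self.stats_mode!r}")
        if not Path(self.manifest).exists():
            raise ConfigError(f"manifest not found: {self.manifest}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "thresholds" in raw:
            raw["thresholds"] = ThresholdSet(
                **{k: tuple(v) for k, v in raw["thresholds"].items()}
            )
        if "morphology" in raw:
            raw["morphology"] = MorphologyParams(**raw["morphology"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    """Paths of the artifacts a pipeline run produced."""

    measures_csv: Path
    variability_csv: Path
    table1_csv: Path
    table2_csv: Path
    qc_csv: Path
    log_path: Path
    n_analysed: int
    n_excluded: int


def mid_slice_comparison(
    measures: pd.DataFrame, mode: str = "auto", alpha: float = 0.05
) -> list[CohortSummary]:
    """Mid-L3 single-slice measures by sex (the conventional snapshot).

    One summary triplet (all / female / male) per measure, built from
    each patient's designated mid slice only.
    """
    mid = measures[measures["is_mid"]]
    out: list[CohortSummary] = []
    for tissue in ("sm", "vat", "sat"):
        for kind, col in _MID_MEASURE_COLS.items():
            g = mid[mid["tissue"] == tissue]
            f = g.loc[g["sex"] == "female", col].astype(float).tolist()
            m = g.loc[g["sex"] == "male", col].astype(float).tolist()
            f = [v for v in f if not math.isnan(v)]
            m = [v for v in m if not math.isnan(v)]
            out.extend(compare_groups(f"{tissue}_{kind}", f, m, mode=mode, alpha=alpha))
    return out


def format_p(p: float) -> str:
    """Render a p-value the way clinical tables print it."""
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return f"{p:.3f}"
    return f"{p:.2f}"


def render_tables(summaries: list[CohortSummary], percent: bool = True) -> pd.DataFrame:
    """Format summaries as ``median% (q25–q75)`` strings with p-values.

    One row per measure with all/female/male columns, mirroring the
    layout of a median-(IQR) cohort table.
    """
    if not summaries:
        raise InsufficientDataError("no summaries to render")
    unit = "%" if percent else ""

    def fmt(s: CohortSummary) -> str:
        if math.isnan(s.median):
            return ""
        return f"{s.median:.2f}{unit} ({s.iqr_low:.2f}–{s.iqr_high:.2f})"

    by_measure: dict[str, dict[str, CohortSummary]] = {}
    for s in summaries:
        by_measure.setdefault(s.measure, {})[s.group] = s
    rows = []
    for measure, groups in by_measure.items():
        p = groups.get("all", next(iter(groups.values()))).p_value
        rows.append(
            {
                "measure": measure,
                "all": fmt(groups["all"]) if "all" in groups else "",
                "female": fmt(groups["female"]) if "female" in groups else "",
                "male": fmt(groups["male"]) if "male" in groups else "",
                "p_value": format_p(p),
            }
        )
    return pd.DataFrame(rows, columns=["measure", "all", "female", "male", "p_value"])


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    return path


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis described in the module docstring.

    A patient whose loading or segmentation fails entirely is excluded
    with the reason logged and recorded in the QC report; QC-flagged
    patients are excluded from the statistics unless
    ``config.include_flagged`` is set.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = pd.read_csv(config.manifest)
    required = {"patient_id", "sex", "age_years", "path", "is_mid"}
    if missing := required - set(manifest.columns):
        raise ConfigError(f"manifest missing columns: {sorted(missing)}")

    all_measures = []
    qc_rows = []
    analysed, excluded = [], []
    for pid, rows in manifest.groupby("patient_id", sort=True):
        pid = str(pid)
        try:
            mid_rows = rows[rows["is_mid"].astype(bool)]
            if len(mid_rows) != 1:
                raise ConfigError(f"patient {pid}: manifest designates {len(mid_rows)} mid slices")
            study = load_study(
                rows["path"].tolist(),
                mid_designation=mid_rows["path"].iloc[0],
                sex=str(rows["sex"].iloc[0]),
                age_years=float(rows["age_years"].iloc[0]),
                patient_id=pid,
            )
            masks = [
                segment_composition(s.hu_image, config.thresholds, config.morphology)
                for s in study.slices
            ]
            qc = qc_study(
                study,
                masks,
                noise_sd_hu=config.qc_noise_sd_hu,
                artefact_bound_hu=config.qc_artefact_bound_hu,
            )
            measures = [measure_slice(s, m) for s, m in zip(study.slices, masks)]
            frame = measures_to_frame(measures)
            frame["sex"] = study.sex
        except L3CompError as exc:
            logger.warning("patient %s failed: %s", pid, exc)
            qc_rows.append(
                {"patient_id": pid, "flags": "processing_error", "included": False, "detail": str(exc)}
            )
            excluded.append(pid)
            continue
        include = qc.passed or config.include_flagged
        qc_rows.append(
            {
                "patient_id": pid,
                "flags": ";".join(sorted(qc.flags)),
                "included": include,
                "detail": "",
            }
        )
        if include:
            all_measures.append(frame)
            analysed.append(pid)
        else:
            excluded.append(pid)

    if not all_measures:
        raise InsufficientDataError("no patient passed loading and QC")
    measures_df = pd.concat(all_measures, ignore_index=True)
    records = build_variability_records(measures_df)
    table2 = sex_comparison(records, mode=config.stats_mode, alpha=config.alpha)
    table1 = mid_slice_comparison(measures_df, mode=config.stats_mode, alpha=config.alpha)

    variability_df = pd.DataFrame(
        [{"patient_id": r.patient_id, "sex": r.sex, **r.values} for r in records]
    )
    result = RunResult(
        measures_csv=_write_csv(measures_df, out_dir / "measures.csv"),
        variability_csv=_write_csv(variability_df, out_dir / "variability.csv"),
        table1_csv=_write_csv(summaries_to_frame(table1), out_dir / "table1.csv"),
        table2_csv=_write_csv(summaries_to_frame(table2), out_dir / "table2.csv"),
        qc_csv=_write_csv(pd.DataFrame(qc_rows), out_dir / "qc_report.csv"),
        log_path=out_dir / "run.log",
        n_analysed=len(analysed),
        n_excluded=len(excluded),
    )
    result.log_path.write_text(
        json.dumps(
            {
                "l3comp_version": __version__,
                "config_hash": config.config_hash(),
                "n_patients_analysed": result.n_analysed,
                "n_patients_excluded": result.n_excluded,
                "excluded": sorted(excluded),
            },
            indent=2,
        )
        + "\n"
    )
    logger.info(
        "pipeline done: %d analysed, %d excluded -> %s",
        result.n_analysed,
        result.n_excluded,
        out_dir,
    )
    return result
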