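"""End-to-end pipeline orchestration and cohort statistics.

``run_pipeline`` chains the four processing stages — viable-myocardium
extraction, surface modeling + cleanup, skeletonization, channel detection —
on one label map and writes all artifacts plus a run manifest (every
parameter and seed), so a run can be reproduced byte-identically.

``summarize_cohort`` aggregates per-case results into the 2x2
detection-vs-inducibility table, per-cohort channel-count means and channel
length mean +/- sd, and tests the association between HT-channel detection
and VT inducibility with Fisher's exact test.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import scipy.stats
import yaml

from . import __version__
from .channels import DetectionParams, detect_ht_channels, write_channel_report
from .meshing import clean_mesh, mask_to_mesh, write_mesh
from .skeleton import ContractionParams, skeletonize, write_skeleton_json
from .volume import LabelVolume, extract_viable, read_labelmap, write_mask

__all__ = [
    "PipelineConfig",
    "CaseResult",
    "CohortSummary",
    "run_pipeline",
    "fisher_exact",
    "summarize_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one pipeline run (defaults are the workflow values:
    30 mm neighborhood, 1 mm scar margin, 100-triangle filter, 90 mm² area,
    3 minimal segments, HT index 26)."""

    neighborhood_mm: float = 30.0
    scar_margin_mm: float = 1.0
    target_faces: int = 10_000
    max_error_mm: float | None = None  # default: 0.5 x max voxel spacing
    min_triangles: int = 100
    contraction: ContractionParams = field(default_factory=ContractionParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = dict(raw)
        if "contraction" in kw:
            kw["contraction"] = ContractionParams(**kw["contraction"])
        if "detection" in kw:
            kw["detection"] = DetectionParams(**kw["detection"])
        return cls(**kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CaseResult:
    case_id: str
    inducible: bool | None
    n_viable_channels: int
    n_ht_channels: int
    channel_lengths_mm: list[float]
    ht_channel_lengths_mm: list[float]
    config: dict
    runtime_s: float

    def __post_init__(self) -> None:
        if self.n_ht_channels > self.n_viable_channels:
            raise ValueError("HT channels cannot outnumber viable channels")


def run_pipeline(
    labels: LabelVolume | str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
    case_id: str = "case",
    inducible: bool | None = None,
) -> CaseResult:
    """Run the full detection workflow on one label map.

    Zero detected channels is a successful outcome.  When ``out_dir`` is
    given, writes: viable mask, cleaned mesh (PLY), skeleton JSON, channel
    CSV/JSON and ``manifest.json``.
    """
    t0 = time.time()
    if not isinstance(labels, LabelVolume):
        labels = read_labelmap(labels)
    stage = "volume"
    try:
        viable = extract_viable(labels, config.neighborhood_mm, config.scar_margin_mm)
        candidates = []
        if viable.grid.any():
            stage = "meshing"
            mesh = mask_to_mesh(viable)
            max_err = (
                0.5 * max(viable.spacing) if config.max_error_mm is None else config.max_error_mm
            )
            mesh = clean_mesh(mesh, config.target_faces, max_err, config.min_triangles)
            if mesh.n_faces:
                stage = "skeletonize"
                graph = skeletonize(mesh, config.contraction, seed=config.seed)
                stage = "channel_detect"
                candidates = detect_ht_channels(viable, graph, config.detection)
            else:
                logger.warning("all mesh components removed as noise; zero channels")
        else:
            logger.warning("empty viable mask (no scar?); zero channels")
            mesh = None
            graph = None
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    result = CaseResult(
        case_id=case_id,
        inducible=inducible,
        n_viable_channels=len(candidates),
        n_ht_channels=sum(c.is_ht for c in candidates),
        channel_lengths_mm=[round(c.length_mm, 6) for c in candidates],
        ht_channel_lengths_mm=[round(c.length_mm, 6) for c in candidates if c.is_ht],
        config=config.to_dict(),
        runtime_s=round(time.time() - t0, 3),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if viable.grid.any():
            write_mask(viable, out_dir / "viable.nrrd")
        if mesh is not None and mesh.n_faces:
            write_mesh(mesh, out_dir / "model.ply")
        if viable.grid.any() and mesh is not None and mesh.n_faces:
            write_skeleton_json(graph, out_dir / "skeleton.json")
        write_channel_report(candidates, out_dir)
        manifest = {
            "case_id": case_id,
            "inducible": inducible,
            "version": __version__,
            "config": config.to_dict(),
            "result": {
                "n_viable_channels": result.n_viable_channels,
                "n_ht_channels": result.n_ht_channels,
                "channel_lengths_mm": result.channel_lengths_mm,
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result


def fisher_exact(table, sided: str = "two") -> tuple[float, bool]:
    """Fisher's exact test on a 2x2 count table.

    Two-sided (default): the p-value sums the probabilities of all tables
    with the observed margins whose hypergeometric probability does not
    exceed the observed one.  Returns ``(p, degenerate)``; a table with an
    empty margin yields p = 1 by convention, flagged degenerate.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer cells")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0, True
    alternative = {"two": "two-sided", "one": "greater"}[sided]
    return float(scipy.stats.fisher_exact(t, alternative=alternative).pvalue), False


def _round_half_up(x: float, decimals: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * decimals), ROUND_HALF_UP))


@dataclass
class CohortSummary:
    detection_table: list[list[int]]  # rows: inducible / non-inducible; cols: HT / no HT
    fisher_p: float | None
    fisher_degenerate: bool
    n_cases: dict
    mean_viable_per_case: dict
    mean_ht_per_case: dict
    length_mean_sd_mm: dict
    raw: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def summarize_cohort(results: list) -> CohortSummary:
    """Aggregate per-case results into cohort statistics.

    Cases with unknown inducibility are excluded from the detection table
    and the test (they still contribute to nothing else).  "HT channel
    detected" per case means at least one HT channel.  Reported means use
    one-decimal round-half-up; raw values are retained under ``raw``.
    """
    known = [r for r in results if r.inducible is not None]
    cohorts = {
        "inducible": [r for r in known if r.inducible],
        "non_inducible": [r for r in known if not r.inducible],
    }
    table = [
        [
            sum(1 for r in cohorts["inducible"] if r.n_ht_channels >= 1),
            sum(1 for r in cohorts["inducible"] if r.n_ht_channels == 0),
        ],
        [
            sum(1 for r in cohorts["non_inducible"] if r.n_ht_channels >= 1),
            sum(1 for r in cohorts["non_inducible"] if r.n_ht_channels == 0),
        ],
    ]
    if known:
        p, degenerate = fisher_exact(table)
        fisher_p = None if degenerate else p
    else:
        logger.warning("no case has known inducibility; skipping Fisher's exact test")
        fisher_p, degenerate = None, True

    def mean_per_case(cases, attr):
        if not cases:
            return None
        return _round_half_up(sum(getattr(r, attr) for r in cases) / len(cases))

    def length_stats(cases):
        lengths = [l for r in cases for l in r.ht_channel_lengths_mm]
        if not lengths:
            return None
        sd = float(np.std(lengths, ddof=1)) if len(lengths) > 1 else None
        return {"mean": float(np.mean(lengths)), "sd": sd, "n": len(lengths)}

    return CohortSummary(
        detection_table=table,
        fisher_p=fisher_p,
        fisher_degenerate=degenerate,
        n_cases={k: len(v) for k, v in cohorts.items()},
        mean_viable_per_case={k: mean_per_case(v, "n_viable_channels") for k, v in cohorts.items()},
        mean_ht_per_case={k: mean_per_case(v, "n_ht_channels") for k, v in cohorts.items()},
        length_mean_sd_mm={k: length_stats(v) for k, v in cohorts.items()},
        raw={
            "per_case": [
                {
                    "case_id": r.case_id,
                    "inducible": r.inducible,
                    "n_viable_channels": r.n_viable_channels,
                    "n_ht_channels": r.n_ht_channels,
                    "channel_lengths_mm": r.channel_lengths_mm,
                }
                for r in results
            ]
        },
    )
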