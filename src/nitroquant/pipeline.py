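"""Pipeline configuration, end-to-end execution, and text reports.

Ties the stages together: read runs, screen MS2 scans for the reporter
pair, cluster and aggregate scan ratios, normalise conditions against the
1:1 reference, and write TSV + human-readable outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chem import (
    HEAVY_REPORTER_MZ,
    LIGHT_REPORTER_MZ,
    N15_N14_DELTA,
    Peptide,
    fragment_ions,
    immonium,
    MODIFICATIONS,
    mz as _mz,
)
from .detect_quant import (
    ChannelMatch,
    NormalizedRatio,
    RatioResult,
    ReporterHit,
    detect_run,
    diagnostic_chromatogram,
    group_and_aggregate,
    normalize,
)
from .spectra_io import read_mzml

__all__ = ["PipelineConfig", "run_pipeline", "masses_report", "hits_to_frame", "frame_to_hits"]

logger = logging.getLogger(__name__)

_POSITIVE_FIELDS = (
    "tolerance_ppm",
    "window_half_width",
    "resolution",
    "precursor_tol_ppm",
    "rt_gap_min",
)


@dataclass
class PipelineConfig:
    """Everything the full pipeline needs, with validated defaults."""

    tolerance_ppm: float = 10.0
    window_half_width: float = 0.001
    corrections: str = "n15"
    resolution: float = 120_000.0
    resolution_mode: str = "at_peak"
    precursor_tol_ppm: float = 10.0
    rt_gap_min: float = 0.5
    intensity_weighted: bool = False
    seed: int = 0
    reference: str | None = None
    conditions: list[str] = field(default_factory=list)
    out_dir: str = "."

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and value > 0):
                raise ValueError(f"config field {name} must be positive, got {value!r}")
        if self.corrections not in ("none", "n15", "n15+c13"):
            raise ValueError(f"unknown corrections mode {self.corrections!r}")
        if self.resolution_mode not in ("at_peak", "orbitrap_sqrt"):
            raise ValueError(f"unknown resolution mode {self.resolution_mode!r}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = repr(sorted(dataclasses.asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


HITS_COLUMNS = [
    "scan_id", "rt_min", "precursor_mz", "z",
    "light_mz", "light_intensity", "light_ppm",
    "heavy_mz", "heavy_intensity", "heavy_ppm",
]


def hits_to_frame(hits: list[ReporterHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "scan_id": h.scan_id,
                "rt_min": h.rt_min,
                "precursor_mz": h.precursor_mz,
                "z": h.precursor_charge,
                "light_mz": h.light.mz if h.light else np.nan,
                "light_intensity": h.light.intensity if h.light else np.nan,
                "light_ppm": h.light.ppm_error if h.light else np.nan,
                "heavy_mz": h.heavy.mz if h.heavy else np.nan,
                "heavy_intensity": h.heavy.intensity if h.heavy else np.nan,
                "heavy_ppm": h.heavy.ppm_error if h.heavy else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=HITS_COLUMNS)


def frame_to_hits(frame: pd.DataFrame) -> list[ReporterHit]:
    hits = []
    for row in frame.itertuples(index=False):
        light = heavy = None
        if not math.isnan(row.light_mz):
            light = ChannelMatch(row.light_mz, row.light_intensity, row.light_ppm)
        if not math.isnan(row.heavy_mz):
            heavy = ChannelMatch(row.heavy_mz, row.heavy_intensity, row.heavy_ppm)
        z = row.z
        hits.append(
            ReporterHit(
                scan_id=str(row.scan_id),
                rt_min=float(row.rt_min),
                precursor_mz=float(row.precursor_mz) if not math.isnan(row.precursor_mz) else None,
                precursor_charge=int(z) if z is not None and not (isinstance(z, float) and math.isnan(z)) else None,
                light=light,
                heavy=heavy,
            )
        )
    return hits


def _match_reference(
    group: RatioResult, reference_groups: list[RatioResult], tol_ppm: float
) -> RatioResult | None:
    best, best_gap = None, math.inf
    for ref in reference_groups:
        tol_da = ref.precursor_mz * tol_ppm * 1e-6
        gap = abs(group.precursor_mz - ref.precursor_mz)
        aligned = min(
            gap,
            abs(gap - N15_N14_DELTA),
            abs(gap - N15_N14_DELTA / 2),
            abs(gap - N15_N14_DELTA / 3),
        )
        if aligned <= tol_da and aligned < best_gap:
            best, best_gap = ref, aligned
    return best


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute detect -> group -> aggregate -> normalise over all runs.

    Writes per-run ``hits_<name>.tsv``, a combined ``ratios.tsv`` and a
    ``summary.txt`` into ``config.out_dir``.  Returns the in-memory results:
    ``{"hits": {...}, "groups": {...}, "normalized": {...}}``.
    """
    if config.conditions and config.reference is None:
        raise ValueError("normalization requested but no reference run given")
    if config.reference is None:
        raise ValueError("a reference run is required")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    run_paths = {"reference": Path(config.reference)}
    for path in config.conditions:
        run_paths[Path(path).stem] = Path(path)

    hits_by_run: dict[str, list[ReporterHit]] = {}
    groups_by_run: dict[str, list[RatioResult]] = {}
    qc_flags: list[str] = []
    for name, path in run_paths.items():
        run = read_mzml(path)
        hits = detect_run(run, config.tolerance_ppm)
        hits_by_run[name] = hits
        if not hits:
            qc_flags.append(f"{name}: no reporter hits")
            logger.warning("run %s: empty hit set", name)
        groups_by_run[name] = group_and_aggregate(
            hits,
            precursor_tol_ppm=config.precursor_tol_ppm,
            rt_gap_min=config.rt_gap_min,
            corrections=config.corrections,
            resolution=config.resolution,
            intensity_weighted=config.intensity_weighted,
        )
        hits_to_frame(hits).to_csv(out_dir / f"hits_{name}.tsv", sep="\t", index=False)

    reference_groups = groups_by_run["reference"]
    normalized: dict[str, list[tuple[RatioResult, NormalizedRatio | None]]] = {}
    rows = []
    for name, groups in groups_by_run.items():
        normalized[name] = []
        for g in groups:
            ref = _match_reference(g, reference_groups, config.precursor_tol_ppm)
            norm = normalize(g, ref) if ref is not None else None
            if ref is None:
                qc_flags.append(f"{name}/{g.group_key}: no matching reference group")
            normalized[name].append((g, norm))
            rows.append(
                {
                    "run": name,
                    "group_id": g.group_key,
                    "precursor_mz": round(g.precursor_mz, 4),
                    "n_scans": g.n,
                    "raw_mean": g.mean,
                    "raw_sd": g.sd,
                    "normalized": norm.value if norm else np.nan,
                    "normalized_sd": (norm.sd if norm and norm.sd is not None else np.nan),
                }
            )
    ratios = pd.DataFrame(
        rows,
        columns=[
            "run", "group_id", "precursor_mz", "n_scans",
            "raw_mean", "raw_sd", "normalized", "normalized_sd",
        ],
    )
    ratios.to_csv(out_dir / "ratios.tsv", sep="\t", index=False)

    buf = io.StringIO()
    buf.write(f"nitroquant {__version__}  config={config.digest()}  seed={config.seed}\n")
    buf.write(
        f"reporter targets: light {LIGHT_REPORTER_MZ:.4f}  heavy {HEAVY_REPORTER_MZ:.4f}  "
        f"tolerance {config.tolerance_ppm} ppm  corrections {config.corrections}\n\n"
    )
    for name in run_paths:
        groups = groups_by_run[name]
        buf.write(
            f"run {name}: {len(hits_by_run[name])} reporter hits, "
            f"{len(groups)} nitropeptide group(s)\n"
        )
        for g, norm in normalized[name]:
            sd = f" +- {g.sd:.4f}" if g.sd is not None else ""
            line = (
                f"  {g.group_key}: n={g.n} raw {g.mean:.4f}{sd}"
            )
            if norm is not None:
                nsd = f" +- {norm.sd:.4f}" if norm.sd is not None else ""
                line += f"  normalized {norm.value:.4f}{nsd}"
            buf.write(line + "\n")
    if qc_flags:
        buf.write("\nQC flags:\n")
        for flag in qc_flags:
            buf.write(f"  - {flag}\n")
    (out_dir / "summary.txt").write_text(buf.getvalue())

    return {
        "hits": hits_by_run,
        "groups": groups_by_run,
        "normalized": normalized,
        "qc_flags": qc_flags,
        "ratios": ratios,
    }


def masses_report(notation: str, max_charge: int = 3) -> str:
    """Mass table for a peptide in text notation.

    Prints the neutral monoisotopic mass, precursor m/z at charges 1 to
    ``max_charge``, the reporter/immonium masses of any nitrotyrosine, and
    the singly charged b/y fragment table.
    """
    pep = Peptide.parse(notation)
    lines = [f"peptide {pep.notation()}"]
    neutral = pep.neutral_mass()
    lines.append(f"neutral monoisotopic mass: {neutral:.4f} Da")
    for z in range(1, max_charge + 1):
        lines.append(f"m/z (+{z}): {_mz(neutral, z):.4f}  ({_mz(neutral, z):.2f} at 2 d.p.)")
    nitro_positions = [
        pos for pos, mod in pep.modifications if mod.name.startswith("nitro")
    ]
    if nitro_positions:
        lines.append(
            f"nitrotyrosine reporter ions: light {LIGHT_REPORTER_MZ:.4f}, "
            f"heavy {HEAVY_REPORTER_MZ:.4f}"
        )
    lines.append("fragments (z=1):")
    for ion in fragment_ions(pep, ("b", "y"), 1):
        lines.append(f"  {ion.label:>5s}  {ion.mz:.4f}")
    return "\n".join(lines)
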