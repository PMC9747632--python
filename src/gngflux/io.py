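"""CSV/TSV readers and writers, run configuration, and report output.

The interchange boundary is plain tabular text: isotopologue tables in long
format (``metabolite, mz_shift, value, kind``), enrichment tables
(``tracer, node, timepoint_min, enrichment``), and flux/report CSVs.  Peak
picking and vendor formats are upstream of this package.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .invitro import ConditionComparison
from .isotopologue import MID, CorrectionSettings, RawIonCounts

__all__ = [
    "RunConfig",
    "load_config",
    "read_mid_table",
    "write_mid_table",
    "read_enrichment_table",
    "write_report",
]

logger = logging.getLogger("gngflux")

MID_COLUMNS = ["metabolite", "mz_shift", "value", "kind"]
#: fraction tables whose sum deviates from 1 by more than this are rejected
FRACTION_SUM_TOLERANCE = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a pipeline run, loaded from YAML."""

    correction: CorrectionSettings = field(default_factory=CorrectionSettings)
    seed: int | None = None
    scheme_set: str = "U13C"
    optimizer_popsize: int = 20
    optimizer_maxiter: int = 250
    n_boot: int = 200
    output_dir: str = "."
    extra: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    correction = CorrectionSettings(
        c13_natural_abundance=raw.pop("c13_natural_abundance", 0.0107),
        tracer_purity=raw.pop("tracer_purity", 0.99),
    )
    known = {
        key: raw.pop(key)
        for key in ("seed", "scheme_set", "optimizer_popsize", "optimizer_maxiter", "n_boot", "output_dir")
        if key in raw
    }
    return RunConfig(correction=correction, extra=raw, **known)


def config_hash(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty input file") from exc
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    return frame


def read_mid_table(path: str | Path) -> list[MID | RawIonCounts]:
    """Parse a long-format isotopologue table into MID/RawIonCounts objects.

    Each metabolite block must declare a single ``kind`` (``fraction`` or
    ``count``) and contiguous mass shifts 0..n.  Fraction blocks whose sum
    is off by at most 5% are renormalized with a logged warning; larger
    deviations are an error.  Malformed rows are reported with their line
    number (1-based, header excluded).
    """
    frame = _read_table(path)
    missing = set(MID_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")

    values = pd.to_numeric(frame["value"], errors="coerce")
    shifts = pd.to_numeric(frame["mz_shift"], errors="coerce")
    bad = frame.index[values.isna() | shifts.isna()].tolist()
    if bad:
        rows = [i + 2 for i in bad]  # +2: header line and 1-based counting
        raise ValueError(f"{path}: non-numeric value/mz_shift at line(s) {rows}")
    frame = frame.assign(value=values, mz_shift=shifts.astype(int))

    out: list[MID | RawIonCounts] = []
    for name, block in frame.groupby("metabolite", sort=False):
        kinds = set(block["kind"])
        if not kinds <= {"fraction", "count"} or len(kinds) != 1:
            raise ValueError(f"{path}: metabolite {name!r} mixes or misstates kinds {kinds}")
        block = block.sort_values("mz_shift")
        expected = list(range(len(block)))
        if block["mz_shift"].tolist() != expected:
            raise ValueError(
                f"{path}: metabolite {name!r} mass shifts must be contiguous 0..n, "
                f"got {block['mz_shift'].tolist()}"
            )
        vec = block["value"].to_numpy()
        if kinds == {"count"}:
            out.append(RawIonCounts(str(name), tuple(vec)))
            continue
        total = vec.sum()
        if abs(total - 1.0) > FRACTION_SUM_TOLERANCE:
            raise ValueError(
                f"{path}: fractions for {name!r} sum to {total:.4g}; "
                f"outside tolerance {FRACTION_SUM_TOLERANCE}"
            )
        if abs(total - 1.0) > 1e-6:
            logger.warning("fractions for %r sum to %.4f; renormalizing", name, total)
        out.append(MID(str(name), tuple(vec), normalize=True))
    return out


def write_mid_table(objects, path: str | Path) -> None:
    """Write MID/RawIonCounts objects in the long CSV dialect."""
    rows = []
    for obj in objects:
        kind = "fraction" if isinstance(obj, MID) else "count"
        vector = obj.fractions if isinstance(obj, MID) else obj.counts
        for shift, value in enumerate(vector):
            rows.append(
                {"metabolite": obj.metabolite_name, "mz_shift": shift, "value": value, "kind": kind}
            )
    pd.DataFrame(rows, columns=MID_COLUMNS).to_csv(path, index=False)


def read_enrichment_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Read ``tracer, node, timepoint_min, enrichment`` rows.

    Returns tracer -> node -> steady-state enrichment (last timepoint).
    When a series has >= 2 timepoints the last two must agree within 10%
    relative, the steady-state criterion for these infusions.
    """
    frame = _read_table(path)
    required = {"tracer", "node", "timepoint_min", "enrichment"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, dict[str, float]] = {}
    for (tracer, node), block in frame.groupby(["tracer", "node"], sort=False):
        series = block.sort_values("timepoint_min")["enrichment"].to_numpy(dtype=float)
        if series.size >= 2 and series[-2] > 0:
            drift = abs(series[-1] - series[-2]) / series[-2]
            if drift >= 0.10:
                raise ValueError(
                    f"{path}: {tracer}/{node} not at steady state "
                    f"(last two timepoints differ by {100 * drift:.1f}%)"
                )
        out.setdefault(str(tracer), {})[str(node)] = float(series[-1])
    return out


def write_report(
    comparison: ConditionComparison,
    out_prefix: str | Path,
    seed: int | None = None,
) -> tuple[Path, Path]:
    """Write a flux-comparison summary as CSV plus human-readable text.

    Columns are emitted in a fixed order and values carry the reporting
    rounding (ratios/folds one decimal, percentages integer), so identical
    inputs produce byte-identical files.
    """
    from . import __version__

    out_prefix = Path(out_prefix)
    rounded = comparison.rounded()
    csv_path = out_prefix.with_suffix(".csv")
    txt_path = out_prefix.with_suffix(".txt")

    frame = pd.DataFrame([rounded], columns=list(rounded))
    frame.insert(0, "seed", [seed])
    frame.insert(0, "gngflux_version", [__version__])
    frame.to_csv(csv_path, index=False)

    folds = comparison.fold_changes()
    lines = [
        f"gngflux {__version__} flux comparison (seed={seed})",
        "",
        f"glycerol:TCA flux ratio  basal {rounded['glycerol_tca_ratio_basal']}"
        f"  stimulated {rounded['glycerol_tca_ratio_stimulated']}",
        f"glycerol share of labeled carbon  basal {rounded['gro_share_basal_pct']}%"
        f"  stimulated {rounded['gro_share_stimulated_pct']}%",
        f"fold changes  glycerol {rounded['gro_fold_change']}"
        f"  pyruvate/lactate {rounded['pl_fold_change']}"
        f"  glutamine {rounded['gln_fold_change']}"
        f"  total {rounded['total_fold_change']}",
        "",
        f"total carbon flux: basal {comparison.basal.total_flux:g}"
        f" -> stimulated {comparison.stimulated.total_flux:g} nmol C/h"
        f" ({folds['total']:.2f}-fold)",
    ]
    txt_path.write_text("\n".join(lines) + "\n")
    return csv_path, txt_path
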