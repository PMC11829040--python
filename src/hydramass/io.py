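"""File formats, run configuration and the two headline pipelines.

Formats (all plain text, dot-decimal):

* extended FASTA — ``>name`` header lines followed by bracket-notation
  sequences (``A[Cm]U[Gm]AA[Y]A[Psi][m5C]UG``);
* peak lists — TSV with columns ``mz`` and ``intensity`` (optional third
  column ``charge``), header optional;
* calibration tables — CSV with columns ``code, amount_pmol, response_ratio``;
* sample tables — CSV with columns ``code, sample, response_ratio`` where
  ``sample`` is ``control`` or ``treated``;
* concentration series — CSV with ``code, hydrazine_pct, remaining_fraction``.

Pipelines:

* :func:`pipeline_fingerprint` — digest -> conversion ladder -> peak matching
  -> pseudouridine inference, the MALDI/HRMS fingerprint workflow;
* :func:`pipeline_quant` — calibration -> amounts -> per-molecule counts ->
  conversion yields (plus dose-response fits when a concentration series is
  supplied), the LC-MS/MS nucleoside quantification workflow.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .chem import MassKind
from .digest import Fragment, Oligo, format_sequence, fragment_mass, t1_digest, tokenize
from .ladder import (
    Assignment,
    MALDI_TOLERANCE_DA,
    MatchResult,
    Peak,
    conversion_ladder,
    infer_nonreactive_sites,
    match_peaks,
    theoretical_peaks,
)
from .quant import (
    CalibrationSeries,
    conversion_yield,
    fit_calibration,
    fit_dose_response,
    per_molecule_counts,
    quantify,
)
from .registry import Registry, TreatmentCondition, load_registry

logger = logging.getLogger("hydramass")

__all__ = [
    "RunConfig",
    "read_extended_fasta",
    "write_extended_fasta",
    "read_peaklist",
    "write_peaklist",
    "write_assignments",
    "write_table",
    "fragments_table",
    "pipeline_fingerprint",
    "pipeline_quant",
]


@dataclass
class RunConfig:
    """Resolved configuration of one analysis run (serialises to YAML)."""

    registry_path: Optional[str] = None
    organism: str = "human"
    tolerance: float = MALDI_TOLERANCE_DA
    tolerance_unit: str = "da"  # "ppm" | "da"
    charges: Tuple[int, ...] = (1,)
    mass_kind: str = "average"  # MALDI default; "monoisotopic" for HRMS
    cyclic_variants: bool = True
    missed_cleavages: int = 0
    condition: Optional[Tuple[float, float, float]] = (30.0, 0.0, 1.0)
    reference_nucleoside: str = "G"
    reference_count: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def treatment_condition(self) -> Optional[TreatmentCondition]:
        if self.condition is None:
            return None
        return TreatmentCondition(*self.condition)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["charges"] = list(self.charges)
        d["condition"] = list(self.condition) if self.condition else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "charges" in d:
            d["charges"] = tuple(d["charges"])
        if d.get("condition") is not None:
            d["condition"] = tuple(d["condition"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_extended_fasta(path: Path, registry: Optional[Registry] = None) -> List[Oligo]:
    """Read bracket-notation sequences from an extended FASTA file."""
    oligos: List[Oligo] = []
    name: Optional[str] = None
    chunks: List[str] = []

    def flush(line_no: int) -> None:
        nonlocal name, chunks
        if name is None and not chunks:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {name!r}")
        try:
            oligos.append(tokenize(seq, registry=registry, name=name))
        except ValueError as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from exc
        name, chunks = None, []

    last_header_line = 0
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush(last_header_line)
                name = line[1:].strip() or None
                last_header_line = i
            else:
                if name is None and not chunks:
                    raise ValueError(f"{path}: line {i}: sequence before first '>' header")
                chunks.append(line)
    flush(last_header_line)
    return oligos


def write_extended_fasta(path: Path, oligos: Sequence[Oligo]) -> None:
    with open(path, "w") as fh:
        for i, o in enumerate(oligos):
            fh.write(f">{o.name or f'oligo{i + 1}'}\n{format_sequence(o.tokens)}\n")


def read_peaklist(path: Path) -> List[Peak]:
    """Read a two/three-column (m/z, intensity[, charge]) TSV peak list."""
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{path}: empty peak list")
        return []
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"mz"}.issubset(df.columns):
        # headerless file: positional columns
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
        df.columns = ["mz", "intensity", "charge"][: df.shape[1]]
    if "mz" not in df.columns:
        raise ValueError(f"{path}: missing required column 'mz'")
    peaks = []
    for _, row in df.iterrows():
        peaks.append(
            Peak(
                mz=float(row["mz"]),
                intensity=float(row["intensity"]) if "intensity" in df.columns and pd.notna(row.get("intensity")) else None,
                charge=int(row["charge"]) if "charge" in df.columns and pd.notna(row.get("charge")) else None,
            )
        )
    if not peaks:
        warnings.warn(f"{path}: peak list contains no peaks")
    return peaks


def write_peaklist(path: Path, peaks: Sequence[Peak]) -> None:
    with open(path, "w") as fh:
        fh.write("mz\tintensity\tcharge\n")
        for p in peaks:
            inten = "" if p.intensity is None else f"{p.intensity:.6g}"
            charge = "" if p.charge is None else str(p.charge)
            fh.write(f"{p.mz:.6f}\t{inten}\t{charge}\n")


def _assignment_row(a: Assignment) -> dict:
    return {
        "observed_mz": a.peak.mz,
        "theoretical_mz": a.peak.mz / (1.0 + a.ppm * 1e-6),
        "ppm": a.ppm,
        "fragment": a.species.fragment.label,
        "sequence": format_sequence(a.species.fragment.tokens),
        "three_prime": a.species.fragment.oligo.three_prime,
        "k": a.species.k,
        "ion": a.ion.label(),
        "rank": a.rank,
        "ambiguous": a.ambiguous,
    }


def write_assignments(path: Path, result: MatchResult, fmt: str = "csv") -> None:
    rows = [_assignment_row(a) for a in result.assignments]
    if fmt == "csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    elif fmt == "json":
        Path(path).write_text(json.dumps(
            {"assignments": rows, "unassigned": [p.mz for p in result.unassigned]},
            indent=2,
        ))
    else:
        raise ValueError("fmt must be 'csv' or 'json'")


def write_table(path: Path, rows: Sequence[dict]) -> None:
    pd.DataFrame(list(rows)).to_csv(path, index=False)


def fragments_table(fragments: Sequence[Fragment], registry: Registry) -> List[dict]:
    rows = []
    for f in fragments:
        rows.append(
            {
                "name": f.parent_name or "",
                "start": f.start,
                "end": f.end,
                "sequence": format_sequence(f.tokens),
                "five_prime": f.oligo.five_prime,
                "three_prime": f.oligo.three_prime,
                "missed_cleavages": f.missed_cleavages,
                "mono_mass": fragment_mass(f, registry, MassKind.MONOISOTOPIC).value,
                "avg_mass": fragment_mass(f, registry, MassKind.AVERAGE).value,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def _report_header(config: RunConfig, registry: Registry) -> dict:
    return {
        "package_version": _pkg_version,
        "registry_version": registry.version,
        "registry_organism": registry.organism,
        "config": config.to_dict(),
    }


def pipeline_fingerprint(
    oligos: Sequence[Oligo],
    peaks: Sequence[Peak],
    config: RunConfig,
    registry: Optional[Registry] = None,
) -> dict:
    """Digest -> ladder -> match -> pseudouridine inference, as one report."""
    registry = registry or load_registry(
        Path(config.registry_path) if config.registry_path else None,
        organism=config.organism,
    )
    condition = config.treatment_condition()
    mass_kind = MassKind(config.mass_kind)

    all_theoretical = []
    fragments: List[Fragment] = []
    for oligo in oligos:
        for frag in t1_digest(oligo, missed_cleavages=config.missed_cleavages):
            fragments.append(frag)
            variants = [frag]
            if config.cyclic_variants and frag.oligo.three_prime == "phosphate":
                cyclic = dataclasses.replace(
                    frag,
                    oligo=dataclasses.replace(frag.oligo, three_prime="cyclic-phosphate"),
                )
                variants.append(cyclic)
            for variant in variants:
                species = conversion_ladder(variant, registry, condition)
                all_theoretical.extend(
                    theoretical_peaks(species, charges=config.charges, mass_kind=mass_kind)
                )

    if peaks and all_theoretical:
        result = match_peaks(
            peaks, all_theoretical,
            tolerance=config.tolerance, unit=config.tolerance_unit,
        )
    else:
        result = MatchResult(assignments=[], unassigned=list(peaks))

    fragment_reports = []
    for frag in fragments:
        inference = infer_nonreactive_sites(result.assignments, frag, registry, condition)
        frag_assignments = [
            _assignment_row(a)
            for a in result.assignments
            if a.species.fragment.tokens == frag.tokens
        ]
        fragment_reports.append(
            {
                "fragment": frag.label,
                "parent": frag.parent_name or "",
                "sequence": format_sequence(frag.tokens),
                "start": frag.start,
                "end": frag.end,
                "assignments": frag_assignments,
                "kmax": inference.kmax,
                "u_positions": inference.u,
                "nonreactive_sites": inference.n_nonreactive,
                "localized": inference.localized,
                "confidence": inference.confidence,
            }
        )
    return {
        **_report_header(config, registry),
        "n_observed_peaks": len(peaks),
        "n_assigned": len(result.assignments),
        "unassigned_mz": [p.mz for p in result.unassigned],
        "fragments": fragment_reports,
    }


def read_calibration_csv(path: Path) -> Dict[str, CalibrationSeries]:
    df = pd.read_csv(path)
    required = {"code", "amount_pmol", "response_ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: calibration table needs columns {sorted(required)}")
    series = {}
    for code, grp in df.groupby("code"):
        series[str(code)] = CalibrationSeries(
            str(code), tuple(zip(grp["amount_pmol"], grp["response_ratio"]))
        )
    return series


def read_sample_csv(path: Path) -> Dict[str, Dict[str, float]]:
    df = pd.read_csv(path)
    required = {"code", "sample", "response_ratio"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample table needs columns {sorted(required)}")
    out: Dict[str, Dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["sample"]), {})[str(row["code"])] = float(row["response_ratio"])
    return out


def pipeline_quant(
    calibration: Dict[str, CalibrationSeries],
    samples: Dict[str, Dict[str, float]],
    config: RunConfig,
    registry: Optional[Registry] = None,
    concentration_series: Optional[pd.DataFrame] = None,
) -> dict:
    """Calibrate, quantify, normalise per molecule and compute yields."""
    registry = registry or load_registry(
        Path(config.registry_path) if config.registry_path else None,
        organism=config.organism,
    )
    curves = {code: fit_calibration(s) for code, s in calibration.items()}

    amounts: Dict[str, Dict[str, float]] = {}
    range_flags: List[str] = []
    for sample_name, ratios in samples.items():
        amounts[sample_name] = {}
        for code, ratio in ratios.items():
            if code not in curves:
                raise KeyError(f"no calibration curve for {code!r} (sample {sample_name!r})")
            q = quantify(ratio, curves[code])
            amounts[sample_name][code] = q.amount_pmol
            if not q.in_range:
                range_flags.append(f"{sample_name}:{code}")

    ref = config.reference_nucleoside
    counts = {
        name: per_molecule_counts(vals, reference=ref, reference_count=config.reference_count)
        for name, vals in amounts.items()
    }

    yields = {}
    if "control" in counts and "treated" in counts:
        for code in counts["control"]:
            if code == ref or code not in counts["treated"]:
                continue
            y = conversion_yield(counts["control"][code], counts["treated"][code])
            yields[code] = {"value": y.value, "raw": y.raw, "clipped": y.clipped}

    dose_fits = {}
    if concentration_series is not None:
        concs = [float(c) for c in concentration_series.columns]
        for code, row in concentration_series.iterrows():
            try:
                fit = fit_dose_response(concs, row.to_numpy(dtype=float))
            except RuntimeError as exc:
                dose_fits[str(code)] = {"error": str(exc)}
                continue
            dose_fits[str(code)] = {
                "ec50": fit.params.ec50,
                "hill": fit.params.hill,
                "ceiling": fit.params.ceiling,
                "stderr": fit.stderr,
                "flags": list(fit.flags),
            }

    return {
        **_report_header(config, registry),
        "calibration": {
            code: {
                "slope": c.slope, "intercept": c.intercept,
                "r_squared": c.r_squared, "valid_range": list(c.valid_range),
            }
            for code, c in curves.items()
        },
        "amounts_pmol": amounts,
        "per_molecule_counts": counts,
        "conversion_yields": yields,
        "out_of_range": range_flags,
        "dose_response": dose_fits,
    }
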