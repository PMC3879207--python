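"""Readers and writers for the formats the pipeline touches.

PWMs are read from MEME-minimal or JASPAR files (via Bio.motifs), assembled
CRMs are written as FASTA plus BED6 motif annotation, measurement tables and
fit reports as TSV, and images as TIFF/PNG.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motifs import CRMDesign, PWM, Site, SiteAnnotation
from .occupancy import ModelParams, PMAD_MOTIF, TIN_MOTIF

__all__ = [
    "PWMParseError",
    "read_pwm",
    "write_crm_fasta_bed",
    "read_crm_fasta_bed",
    "read_measurements",
    "write_measurements",
    "read_designs",
    "write_designs",
    "write_fit_report",
    "write_image",
    "read_image",
]

_DEFAULT_MOTIFS = {"pMad": PMAD_MOTIF, "Tin": TIN_MOTIF}


class PWMParseError(ValueError):
    """Raised when a motif file cannot be parsed; names the offending file."""


def _sniff_format(text: str) -> str:
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.upper().startswith("MEME VERSION"):
            return "minimal"
        return "jaspar"
    raise PWMParseError("file is empty")


def read_pwm(path: str | Path, pseudocount: float = 0.5) -> list[PWM]:
    """Read PWMs from a MEME-minimal or JASPAR motif file.

    JASPAR count matrices are converted to probabilities with a small
    pseudocount; MEME-minimal letter-probability matrices are renormalized
    per position. Malformed files raise :class:`PWMParseError` naming the
    file; no partial result is returned.
    """
    path = Path(path)
    text = path.read_text()
    try:
        fmt = _sniff_format(text)
        parsed = bio_motifs.parse(_stdio.StringIO(text), fmt)
        result = []
        for m in parsed:
            counts = np.array([list(m.counts[b]) for b in "ACGT"], dtype=float).T
            if counts.size == 0:
                raise ValueError("motif with no positions")
            counts = counts + pseudocount
            probs = counts / counts.sum(axis=1, keepdims=True)
            name = m.name or m.base_id or f"motif_{len(result) + 1}"
            result.append(PWM(name=name, matrix=probs))
        if not result:
            raise ValueError("no motifs found")
        return result
    except PWMParseError:
        raise
    except Exception as exc:
        raise PWMParseError(f"{path}: cannot parse motif file ({exc})") from exc


# ---------------------------------------------------------------------------
# FASTA + BED6
# ---------------------------------------------------------------------------

def write_crm_fasta_bed(
    names: Sequence[str],
    sequences: Sequence[str],
    annotations: Sequence[Sequence[SiteAnnotation]],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write assembled CRMs to ``<prefix>.fa`` and ``<prefix>.bed``.

    BED6 rows use the CRM name as chromosome, the TF name as feature name,
    score 0, and the strand column for site orientation.
    """
    out_prefix = Path(out_prefix)
    fasta_path = out_prefix.with_suffix(".fa")
    bed_path = out_prefix.with_suffix(".bed")
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in zip(names, sequences)
    ]
    SeqIO.write(records, fasta_path, "fasta")
    with open(bed_path, "w") as handle:
        for sites in annotations:
            for s in sites:
                handle.write(
                    f"{s.crm_name}\t{s.start}\t{s.end}\t{s.tf_name}\t0\t{s.strand}\n"
                )
    return fasta_path, bed_path


def read_crm_fasta_bed(
    out_prefix: str | Path,
) -> tuple[dict[str, str], list[SiteAnnotation]]:
    """Round-trip reader for :func:`write_crm_fasta_bed` output."""
    out_prefix = Path(out_prefix)
    seqs = {
        # CRM names may contain spaces; the full header line is the name
        (rec.description or rec.id): str(rec.seq)
        for rec in SeqIO.parse(out_prefix.with_suffix(".fa"), "fasta")
    }
    annotations = []
    with open(out_prefix.with_suffix(".bed")) as handle:
        for line in handle:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")
            annotations.append(
                SiteAnnotation(chrom, int(start), int(end), name, strand)
            )
    return seqs, annotations


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

_MEASUREMENT_COLUMNS = [
    "line", "tissue", "n_embryos", "n_active", "penetrance", "penetrance_se",
    "n_expressivity_embryos", "expressivity", "expressivity_se", "domain_calls",
]


def write_measurements(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a MeasurementTable as TSV (domain calls serialized per embryo)."""
    path = Path(path)
    cols = [c for c in _MEASUREMENT_COLUMNS if c in table.columns]
    table.to_csv(path, sep="\t", index=False, columns=cols)
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a MeasurementTable TSV."""
    table = pd.read_csv(path, sep="\t", dtype={"domain_calls": str})
    missing = {"line", "tissue", "penetrance"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing measurement columns {sorted(missing)}")
    return table


def parse_domain_calls(serialized: str) -> np.ndarray:
    """Decode a 'per-embryo;comma-separated 0/1' domain-call string."""
    if not serialized or (isinstance(serialized, float) and np.isnan(serialized)):
        return np.zeros((0, 0), dtype=bool)
    rows = [
        [bool(int(v)) for v in embryo.split(",")] for embryo in serialized.split(";")
    ]
    return np.array(rows, dtype=bool)


# ---------------------------------------------------------------------------
# Design specifications
# ---------------------------------------------------------------------------

def write_designs(designs: Sequence[CRMDesign], path: str | Path) -> Path:
    """Write CRM design records as a YAML document."""
    docs = [
        {
            "name": d.name,
            "tfs": list(d.tf_names),
            "orientations": ["S" if s.orientation == "sense" else "A" for s in d.sites],
            "sequences": [s.sequence for s in d.sites],
            "spacings": list(d.spacings),
        }
        for d in designs
    ]
    path = Path(path)
    path.write_text(yaml.safe_dump({"designs": docs}, sort_keys=False))
    return path


def read_designs(path: str | Path) -> list[CRMDesign]:
    """Read CRM design records from YAML.

    Each record gives ordered TF names, orientations (S/A), and spacings in
    bp; motif sequences may be given explicitly or, for pMad/Tin, fall back
    to the package's canonical instances.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "designs" not in data:
        raise ValueError(f"{path}: expected a top-level 'designs' list")
    designs = []
    for rec in data["designs"]:
        tfs = rec["tfs"]
        orients = rec.get("orientations", ["S"] * len(tfs))
        seqs = rec.get("sequences")
        sites = []
        for i, tf in enumerate(tfs):
            seq = seqs[i] if seqs else _DEFAULT_MOTIFS.get(tf)
            if seq is None:
                raise ValueError(
                    f"{path}: no sequence for TF {tf!r} and no default available"
                )
            orientation = "sense" if orients[i].upper().startswith("S") else "antisense"
            sites.append(Site(tf, seq, orientation))
        designs.append(CRMDesign(rec["name"], tuple(sites), tuple(rec["spacings"])))
    return designs


# ---------------------------------------------------------------------------
# Fit reports and images
# ---------------------------------------------------------------------------

def write_fit_report(
    params: ModelParams,
    residual: float,
    per_crm: pd.DataFrame,
    out_prefix: str | Path,
    extra: dict | None = None,
) -> tuple[Path, Path]:
    """Write a fit as ``<prefix>.tsv`` (per-CRM) + ``<prefix>.json`` (summary)."""
    out_prefix = Path(out_prefix)
    tsv = out_prefix.with_suffix(".tsv")
    js = out_prefix.with_suffix(".json")
    per_crm.to_csv(tsv, sep="\t", index=False)
    summary = {"params": asdict(params), "residual": residual}
    if extra:
        summary.update(extra)
    js.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return tsv, js


def write_image(image_array: np.ndarray, path: str | Path) -> Path:
    """Write one channel as TIFF (float) or PNG (rescaled to 16-bit)."""
    import imageio.v3 as iio

    path = Path(path)
    arr = np.asarray(image_array)
    if path.suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, arr.astype(np.float32))
    else:
        top = float(arr.max()) or 1.0
        iio.imwrite(path, (np.clip(arr / top, 0, 1) * 65535).astype(np.uint16))
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read one channel written by :func:`write_image` back as float."""
    import imageio.v3 as iio

    path = Path(path)
    arr = np.asarray(iio.imread(path)).astype(float)
    if path.suffix.lower() not in (".tif", ".tiff"):
        arr = arr / 65535.0
    return arr
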