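"""Readers and writers for every on-disk format the pipeline touches.

Canonical formats:

* **genotype matrix** — tab-separated; header row ``sample_id`` followed by
  marker ids; one row per sample with calls encoded ``0/1/2/NA`` (``NA`` is
  case-sensitive). Lossless round-trip with :func:`read_matrix`.
* **GenomeStudio-style "Final Report"** — long-format TSV with columns
  ``Sample ID, SNP Name, Allele1, Allele2`` (an optional ``[Header]`` /
  ``[Data]`` preamble is skipped). Read-only.
* **panel file** — TSV of marker id, chromosome, position, alleles, MAF.
* **VCF 4.2 export** — one record per panel marker, GT-only.
* **manifest** — YAML/JSON round-trip of the simulation ground truth.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import MISSING, GenotypeVector
from .markers import SnpMarker, SnpPanel
from .simulate import CohortManifest

_CALL_TO_STR = {0: "0", 1: "1", 2: "2", MISSING: "NA"}
_STR_TO_CALL = {"0": 0, "1": 1, "2": 2, "NA": MISSING}

FINAL_REPORT_COLUMNS = ("Sample ID", "SNP Name", "Allele1", "Allele2")


class FormatError(ValueError):
    """Raised when a file does not conform to its declared dialect."""


def _check_aligned(samples: Sequence[GenotypeVector], panel: SnpPanel) -> None:
    for s in samples:
        if len(s) != panel.size:
            raise FormatError(
                f"sample {s.sample_id!r} has {len(s)} calls, panel has {panel.size}"
            )


# ---------------------------------------------------------------------------
# genotype matrix dialect


def write_matrix(samples: Sequence[GenotypeVector], panel: SnpPanel, path) -> None:
    """Write genotype vectors in the canonical tab-separated matrix dialect."""
    _check_aligned(samples, panel)
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(panel.marker_ids) + "\n")
        for s in samples:
            row = "\t".join(_CALL_TO_STR[int(c)] for c in s.calls)
            fh.write(f"{s.sample_id}\t{row}\n")


def read_matrix(path, panel: SnpPanel) -> list[GenotypeVector]:
    """Read the matrix dialect, validating marker ids and order against panel."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, index_col=0, keep_default_na=False
    )
    file_markers = list(df.columns)
    expected = panel.marker_ids
    if file_markers != expected:
        for i, (got, want) in enumerate(zip(file_markers, expected)):
            if got != want:
                raise FormatError(
                    f"{path}: marker column {i} is {got!r}, panel expects {want!r}"
                )
        raise FormatError(
            f"{path}: {len(file_markers)} marker columns, panel has {panel.size}"
        )
    samples = []
    for sample_id, row in df.iterrows():
        try:
            calls = np.array([_STR_TO_CALL[v] for v in row], dtype=np.int8)
        except KeyError as e:
            raise FormatError(
                f"{path}: sample {sample_id!r} has invalid call token {e.args[0]!r}"
            ) from None
        samples.append(GenotypeVector(str(sample_id), calls))
    return samples


# ---------------------------------------------------------------------------
# GenomeStudio-style long format


def _final_report_rows(path):
    """Yield data rows, skipping an optional [Header]..[Data] preamble."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    for i, line in enumerate(lines):
        if line.strip() == "[Data]":
            start = i + 1
            break
    if start == 0 and lines and lines[0].strip().startswith("["):
        raise FormatError(f"{path}: section preamble present but no [Data] section")
    return lines[start:]


def read_final_report(path, panel: SnpPanel) -> list[GenotypeVector]:
    """Assemble genotype vectors from a long-format allele-call export.

    Allele pairs are mapped onto genotype states against the panel's
    major/minor alleles; heterozygotes are unordered, ``-`` (or an empty
    field) denotes a failed call. Samples appear in file order; markers are
    reordered to panel order, with markers absent from the file left
    MISSING. Unknown marker names or alleles raise :class:`FormatError`.
    """
    lines = _final_report_rows(path)
    if not lines:
        raise FormatError(f"{path}: empty final report")
    header = lines[0].split("\t")
    try:
        col = {name: header.index(name) for name in FINAL_REPORT_COLUMNS}
    except ValueError:
        raise FormatError(
            f"{path}: header must contain columns {FINAL_REPORT_COLUMNS}, got {header}"
        ) from None

    order: list[str] = []
    calls: dict[str, np.ndarray] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        sample = fields[col["Sample ID"]]
        snp = fields[col["SNP Name"]]
        a1 = fields[col["Allele1"]].strip()
        a2 = fields[col["Allele2"]].strip()
        if snp not in panel:
            raise FormatError(f"{path}: unknown marker {snp!r} (sample {sample!r})")
        idx = panel.index_of(snp)
        marker = panel[idx]
        if sample not in calls:
            order.append(sample)
            calls[sample] = np.full(panel.size, MISSING, dtype=np.int8)
        pair = (a1 or "-", a2 or "-")
        if pair == ("-", "-"):
            continue  # already MISSING
        valid = {marker.allele_a, marker.allele_b}
        for allele in pair:
            if allele not in valid:
                raise FormatError(
                    f"{path}: allele {allele!r} at marker {snp!r} "
                    f"(sample {sample!r}) not in {sorted(valid)} or '-'"
                )
        calls[sample][idx] = sum(a == marker.allele_b for a in pair)
    return [GenotypeVector(s, calls[s]) for s in order]


# ---------------------------------------------------------------------------
# VCF export


def export_vcf(samples: Sequence[GenotypeVector], panel: SnpPanel, path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotypes, one record per marker."""
    _check_aligned(samples, panel)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    chroms = []
    for m in panel:
        if m.chromosome not in chroms:
            chroms.append(m.chromosome)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pdxdrift\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        cols += [s.sample_id for s in samples]
        fh.write("\t".join(cols) + "\n")
        for i, m in enumerate(panel):
            gts = "\t".join(gt_map[int(s.calls[i])] for s in samples)
            fh.write(
                f"{m.chromosome}\t{m.position}\t{m.marker_id}\t{m.allele_a}\t"
                f"{m.allele_b}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# panel file


def write_panel(panel: SnpPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tchromosome\tposition\tallele_a\tallele_b\tmaf\n")
        for m in panel:
            fh.write(
                f"{m.marker_id}\t{m.chromosome}\t{m.position}\t"
                f"{m.allele_a}\t{m.allele_b}\t{m.maf:.6g}\n"
            )


def read_panel(path, maf_threshold: float | None = None) -> SnpPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"marker_id", "chromosome", "position", "allele_a", "allele_b", "maf"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: panel file missing columns {sorted(missing_cols)}")
    markers = [
        SnpMarker(
            marker_id=str(r.marker_id),
            chromosome=str(r.chromosome),
            position=int(r.position),
            allele_a=str(r.allele_a),
            allele_b=str(r.allele_b),
            maf=float(r.maf),
        )
        for r in df.itertuples()
    ]
    return SnpPanel(markers, maf_threshold=maf_threshold)


# ---------------------------------------------------------------------------
# manifest


def write_manifest(manifest: CohortManifest, path) -> None:
    """Serialize a cohort manifest as YAML (or JSON for a .json path)."""
    path = Path(path)
    data = manifest.to_dict()
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2, sort_keys=True)
        else:
            yaml.safe_dump(data, fh, sort_keys=True)


def read_manifest(path) -> CohortManifest:
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return CohortManifest.from_dict(data)
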