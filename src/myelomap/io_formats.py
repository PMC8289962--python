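"""Tabular I/O: SV-TSV dialects, CNV tables, BED panels, BEDPE/circos exports.

The canonical exchange format is a tab-separated SV table with a header.  A
dialect object maps column names onto the ten required roles, so Bionano
SMAP-style exports can be ingested by supplying a different column map; a
``smap_dialect()`` preset is provided.  Internally everything is 1-based
inclusive; BED I/O converts to/from 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .datamodel import (
    CNVSegment,
    FormatError,
    GenePanel,
    GenomeModel,
    GenomicBreakpoint,
    SampleMeta,
    SVCall,
    _data_path,
    load_genome_model,
    normalize_chrom,
    validate_call,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SvTableDialect",
    "canonical_dialect",
    "smap_dialect",
    "read_sv_table",
    "write_sv_table",
    "read_cnv_table",
    "write_cnv_table",
    "read_bed",
    "write_bed",
    "export_bedpe",
    "export_circos_links",
    "load_chr1_cohort_fixture",
]

_ROLES = (
    "sample_id",
    "pipeline",
    "sv_type",
    "chrom_a",
    "pos_a",
    "chrom_b",
    "pos_b",
    "size",
    "vaf",
    "n_molecules",
)

# columns that round-trip optional SVCall fields when present
_OPTIONAL_COLUMNS = (
    "call_id",
    "somatic_status",
    "cnv_support",
    "provenance",
    "original_type",
    "size_bin",
    "clonality",
    "n_genes",
)


@dataclass(frozen=True)
class SvTableDialect:
    """Column map and conventions of one SV-TSV flavour."""

    columns: dict  # role -> column name, all ten _ROLES mapped
    size_unit: str = "bp"  # "bp" or "kbp"
    type_map: dict = field(default_factory=dict)  # input token -> canonical type

    def __post_init__(self) -> None:
        missing = [r for r in _ROLES if r not in self.columns]
        if missing:
            raise FormatError(f"dialect misses roles: {missing}")
        if self.size_unit not in ("bp", "kbp"):
            raise FormatError(f"size unit must be bp or kbp, got {self.size_unit!r}")

    def canonical_type(self, token: str) -> str:
        return self.type_map.get(token, token)


_DEFAULT_TYPE_MAP = {
    "Deletion": "deletion",
    "Insertion": "insertion",
    "Duplication": "duplication",
    "Inversion": "inversion",
    "Translocation": "translocation_inter",
    "Intra-chrom": "intra_rearrangement",
}


def canonical_dialect() -> SvTableDialect:
    """The package's own SV-TSV dialect (sizes in bp)."""
    columns = {r: r for r in _ROLES}
    columns["size"] = "size_bp"
    columns["vaf"] = "vaf_pct"
    return SvTableDialect(columns=columns, size_unit="bp", type_map=dict(_DEFAULT_TYPE_MAP))


def smap_dialect() -> SvTableDialect:
    """Preset mapping Bionano SMAP-style column names onto the ten roles."""
    return SvTableDialect(
        columns={
            "sample_id": "Sample",
            "pipeline": "Algorithm",
            "sv_type": "Type",
            "chrom_a": "RefcontigID1",
            "pos_a": "RefStartPos",
            "chrom_b": "RefcontigID2",
            "pos_b": "RefEndPos",
            "size": "SVsize",
            "vaf": "VAF",
            "n_molecules": "SelfMolecules",
        },
        size_unit="bp",
        type_map={
            "deletion": "deletion",
            "insertion": "insertion",
            "duplication": "duplication",
            "inversion": "inversion",
            "translocation_interchr": "translocation_inter",
            "translocation_intrachr": "intra_rearrangement",
            **_DEFAULT_TYPE_MAP,
        },
    )


def _parse_number(text: str, line_no: int, column: str) -> float:
    """Parse a number accepting thousands separators (``14,502``)."""
    try:
        return float(str(text).replace(",", "").strip())
    except ValueError:
        raise FormatError(f"line {line_no}: unparseable number {text!r} in {column}") from None


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() in ("", ".", "nan", "NA")


def read_sv_table(
    path,
    dialect: Optional[SvTableDialect] = None,
    genome: Optional[GenomeModel] = None,
) -> list:
    """Read an SV table into validated ``SVCall`` records.

    Sizes in kbp dialects are converted to bp; rows failing ``validate_call``
    are rejected with their line numbers.
    """
    dialect = dialect or canonical_dialect()
    genome = genome if genome is not None else load_genome_model("hg38")
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot read SV table: {exc}") from exc
    missing = [c for r, c in dialect.columns.items() if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mapped columns {missing}")

    calls: list[SVCall] = []
    bad_rows: list[str] = []
    for idx, row in frame.iterrows():
        line_no = idx + 2  # header is line 1
        get = lambda role: row[dialect.columns[role]]
        sv_type = dialect.canonical_type(str(get("sv_type")).strip())
        size_raw = get("size")
        if _is_missing(size_raw):
            size_bp = None
        else:
            size = _parse_number(size_raw, line_no, dialect.columns["size"])
            if dialect.size_unit == "kbp":
                size = size * 1000
            if size < 0:
                raise FormatError(f"line {line_no}: negative size {size_raw!r}")
            size_bp = int(round(size))
        vaf_raw = get("vaf")
        vaf = None if _is_missing(vaf_raw) else _parse_number(vaf_raw, line_no, dialect.columns["vaf"])
        nmol_raw = get("n_molecules")
        n_molecules = 0 if _is_missing(nmol_raw) else int(_parse_number(nmol_raw, line_no, dialect.columns["n_molecules"]))
        kwargs = {}
        for col in _OPTIONAL_COLUMNS:
            if col in frame.columns and not _is_missing(row[col]):
                value = str(row[col]).strip()
                if col == "provenance":
                    kwargs[col] = frozenset(value.split("+")) if value else frozenset()
                elif col == "n_genes":
                    kwargs[col] = int(_parse_number(value, line_no, col))
                else:
                    kwargs[col] = value
        call_id = kwargs.pop("call_id", f"{path.stem}_{idx:05d}")
        call = SVCall(
            call_id=call_id,
            sample_id=str(get("sample_id")).strip(),
            pipeline=str(get("pipeline")).strip(),
            sv_type=sv_type,
            bp_a=GenomicBreakpoint(get("chrom_a"), int(_parse_number(get("pos_a"), line_no, "pos_a"))),
            bp_b=GenomicBreakpoint(get("chrom_b"), int(_parse_number(get("pos_b"), line_no, "pos_b"))),
            size_bp=size_bp,
            vaf_pct=vaf,
            n_molecules=n_molecules,
            **kwargs,
        )
        problems = validate_call(call, genome)
        if problems:
            bad_rows.append(f"line {line_no}: {'; '.join(problems)}")
        else:
            calls.append(call)
    if bad_rows:
        raise FormatError(f"{path}: invalid rows rejected:\n" + "\n".join(bad_rows))
    return calls


def write_sv_table(calls: Iterable[SVCall], path, dialect: Optional[SvTableDialect] = None) -> Path:
    """Write calls as SV-TSV; ``read_sv_table`` of the result is the identity."""
    dialect = dialect or canonical_dialect()
    inverse_types = {v: k for k, v in dialect.type_map.items()}
    path = Path(path)
    rows = []
    for c in calls:
        size = c.size_bp
        if size is not None and dialect.size_unit == "kbp":
            size = size / 1000
        row = {
            dialect.columns["sample_id"]: c.sample_id,
            dialect.columns["pipeline"]: c.pipeline,
            dialect.columns["sv_type"]: inverse_types.get(c.sv_type, c.sv_type),
            dialect.columns["chrom_a"]: c.bp_a.chrom,
            dialect.columns["pos_a"]: c.bp_a.pos,
            dialect.columns["chrom_b"]: c.bp_b.chrom,
            dialect.columns["pos_b"]: c.bp_b.pos,
            dialect.columns["size"]: "" if size is None else size,
            dialect.columns["vaf"]: "" if c.vaf_pct is None else c.vaf_pct,
            dialect.columns["n_molecules"]: c.n_molecules,
            "call_id": c.call_id,
            "somatic_status": c.somatic_status,
            "cnv_support": c.cnv_support,
            "provenance": "+".join(sorted(c.provenance)),
            "original_type": c.original_type or "",
            "size_bin": c.size_bin or "",
            "clonality": c.clonality or "",
            "n_genes": "" if c.n_genes is None else c.n_genes,
        }
        rows.append(row)
    columns = [dialect.columns[r] for r in _ROLES] + list(_OPTIONAL_COLUMNS)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_cnv_table(path) -> list:
    """Read a CNV segment TSV (sample_id, chrom, start, end, copy_number).

    Segments of one sample on one chromosome must not overlap.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("sample_id", "chrom", "start", "end", "copy_number")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing CNV columns {missing}")
    segments = []
    for idx, row in frame.iterrows():
        line_no = idx + 2
        try:
            segments.append(
                CNVSegment(
                    sample_id=str(row["sample_id"]).strip(),
                    chrom=row["chrom"],
                    start=int(_parse_number(row["start"], line_no, "start")),
                    end=int(_parse_number(row["end"], line_no, "end")),
                    copy_number=int(_parse_number(row["copy_number"], line_no, "copy_number")),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {line_no}: {exc}") from exc
    overlaps = []
    keyed: dict = {}
    for seg in segments:
        keyed.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sample, chrom), segs in keyed.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start <= prev.end:
                overlaps.append(
                    f"{sample} chr{chrom}: {prev.start}-{prev.end} overlaps {cur.start}-{cur.end}"
                )
    if overlaps:
        raise FormatError(f"{path}: overlapping CNV segments:\n" + "\n".join(overlaps))
    return segments


def write_cnv_table(segments: Iterable[CNVSegment], path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "copy_number": s.copy_number,
            }
            for s in segments
        ],
        columns=["sample_id", "chrom", "start", "end", "copy_number"],
    )
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_bed(path, name: Optional[str] = None) -> GenePanel:
    """Read a BED file (0-based half-open) into a 1-based inclusive panel.

    The 4th column is used as the symbol when present, else one is
    synthesised; a 5th column, when non-numeric, is read as comma-separated
    category tags.
    """
    path = Path(path)
    name = name or path.stem
    genes = []
    categories = {}
    seen = set()
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {line_no}: BED needs >= 3 columns")
        try:
            start0, end0 = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"{path}: line {line_no}: unparseable coordinates") from None
        if end0 <= start0 or start0 < 0:
            raise FormatError(f"{path}: line {line_no}: end <= start in BED interval")
        chrom = normalize_chrom(fields[0])
        symbol = fields[3].strip() if len(fields) > 3 and fields[3].strip() else f"{name}_{line_no}"
        if symbol in seen:  # collapse multiple transcript intervals per symbol
            for i, (c, s, e, sym) in enumerate(genes):
                if sym == symbol:
                    genes[i] = (c, min(s, start0 + 1), max(e, end0), sym)
                    break
            continue
        seen.add(symbol)
        genes.append((chrom, start0 + 1, end0, symbol))
        if len(fields) > 4 and fields[4].strip() and not fields[4].strip().replace(".", "").isdigit():
            categories[symbol] = frozenset(fields[4].split(","))
    return GenePanel(name=name, genes=genes, categories=categories)


def write_bed(panel: GenePanel, path, add_chr_prefix: bool = True) -> Path:
    """Write a panel back to BED (0-based half-open); inverse of ``read_bed``."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end, symbol in panel.genes:
            label = f"chr{chrom}" if add_chr_prefix else chrom
            fh.write(f"{label}\t{start - 1}\t{end}\t{symbol}\n")
    return path


def _bedpe_blocks(call: SVCall) -> tuple:
    a, b = call.bp_a, call.bp_b
    return (f"chr{a.chrom}", a.pos - 1, a.pos, f"chr{b.chrom}", b.pos - 1, b.pos)


def export_bedpe(calls: Iterable[SVCall], path) -> Path:
    """Write two-breakpoint calls as BEDPE (0-based half-open blocks)."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in calls:
            ca, sa, ea, cb, sb, eb = _bedpe_blocks(c)
            score = "." if c.vaf_pct is None else f"{c.vaf_pct:g}"
            fh.write(f"{ca}\t{sa}\t{ea}\t{cb}\t{sb}\t{eb}\t{c.call_id}\t{score}\t.\t.\n")
    return path


def export_circos_links(calls: Iterable[SVCall], path) -> Path:
    """Write circos link lines; the value column carries VAF (drives line
    thickness/colour in circos-style figures)."""
    path = Path(path)
    with open(path, "w") as fh:
        for c in calls:
            ca, sa, ea, cb, sb, eb = _bedpe_blocks(c)
            value = 0.0 if c.vaf_pct is None else c.vaf_pct
            fh.write(f"{ca}\t{sa}\t{ea}\t{cb}\t{sb}\t{eb}\t{value:g}\n")
    return path


def load_chr1_cohort_fixture() -> tuple:
    """Load the packaged chromosome-1 SV table of the 11-patient cohort.

    Returns ``(calls, meta)``: one validated ``SVCall`` per published row
    (printed kbp sizes converted exactly to bp; the printed affected-gene
    count stored as the ``n_genes`` annotation; VAF as printed) and one
    ``SampleMeta`` per patient (4 EMM, 7 MM).  Molecule support is not
    printed in the source table; records carry the minimum (10) consistent
    with the molecule-support filter every published call passed.
    """
    path = _data_path("chr1_cohort_svs.tsv")
    genome = load_genome_model("hg38")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    meta_map: dict = {}
    for idx, row in frame.iterrows():
        line_no = idx + 2
        sample = row["sample_id"]
        meta_map.setdefault(sample, SampleMeta(sample_id=sample, group=row["group"]))
        sv_type = _DEFAULT_TYPE_MAP[row["sv_type"]]
        if _is_missing(row["size_kbp"]):
            size_bp = None
        else:
            # exact kbp -> bp conversion of the printed size
            text = row["size_kbp"].replace(",", "")
            whole, _, frac = text.partition(".")
            size_bp = int(whole) * 1000 + int((frac + "000")[:3] or 0)
        call = SVCall(
            call_id=f"{sample}_{idx:03d}",
            sample_id=sample,
            pipeline="merged",
            sv_type=sv_type,
            bp_a=GenomicBreakpoint(row["chrom_a"], int(row["pos_a"])),
            bp_b=GenomicBreakpoint(row["chrom_b"], int(row["pos_b"])),
            size_bp=size_bp,
            vaf_pct=float(row["vaf_pct"]),
            n_molecules=10,
            somatic_status="somatic_like",
            provenance=frozenset({"de_novo", "rare_variant"}),
            n_genes=None if _is_missing(row["n_genes"]) else int(row["n_genes"]),
        )
        problems = validate_call(call, genome)
        if problems:
            raise FormatError(f"fixture line {line_no}: {problems}")
        calls.append(call)
    order = sorted(meta_map, key=lambda s: (meta_map[s].group, s))
    return calls, [meta_map[s] for s in order]
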