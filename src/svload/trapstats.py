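"""Point-in-interval genomics: SNPs trapped within SVs, exonic overlap, SV tallies.

All coordinates are handled 1-based with inclusive spans internally.  BED
input (0-based, half-open) is normalized on read.  Containment at interval
boundaries is inclusive: a point at ``start`` or ``end`` is inside.

Structural-variant spans follow VCF conventions: a spanning record (DEL,
DUP, INV) covers [POS, END], falling back to [POS, POS+|SVLEN|-1] when END
is absent; insertions are anchored at a single nucleotide [POS, POS] for
containment but contribute |SVLEN| inserted nucleotides to the per-type
totals; translocation breakends are 1-nt anchors.

Queries use a per-chromosome sorted sweep (interval starts sorted, running
maximum of ends), giving O((n+m) log(n+m)) overall; a point is counted once
no matter how many intervals contain it, and an interval once no matter how
many features it touches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SVTYPES = ("INS", "DEL", "DUP", "INV", "TRA", "NA")
_SPANNING = {"DEL", "DUP", "INV"}

__all__ = [
    "PointVariant",
    "IntervalVariant",
    "OverlapReport",
    "SVTYPES",
    "read_point_variants",
    "read_interval_variants",
    "read_feature_intervals",
    "trapped_fraction",
    "feature_overlap_counts",
    "nucleotides_by_svtype",
    "per_chromosome_sv_counts",
    "compute_overlap_report",
    "write_overlap_report",
    "synth_variant_pair",
    "SynthSpec",
    "GenerationError",
]


class GenerationError(ValueError):
    """Raised when a synthetic fixture request cannot be satisfied."""


@dataclass(frozen=True)
class PointVariant:
    """A point variant (SNP): chromosome, 1-based position, optional label."""

    chrom: str
    pos: int
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")


@dataclass(frozen=True)
class IntervalVariant:
    """A structural variant with a 1-based inclusive span and a class label.

    ``length`` is the number of nucleotides affected, which for insertions
    is the inserted length rather than the 1-nt anchor span.
    """

    chrom: str
    start: int
    end: int
    svtype: str = "NA"
    length: int = 0
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"need 1 <= start <= end, got [{self.start}, {self.end}]")
        if self.svtype not in SVTYPES:
            raise ValueError(f"svtype must be one of {SVTYPES}, got {self.svtype!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass
class OverlapReport:
    """Trapped/exonic/per-chromosome tallies over one variant set."""

    total_points: int = 0
    trapped_points: int = 0
    trapped_fraction: float = 0.0
    trapped_fraction_defined: bool = True
    exonic_points: Optional[int] = None
    exonic_intervals: Optional[int] = None
    per_chrom_by_type: Dict[str, Dict[str, int]] = field(default_factory=dict)
    nt_by_type: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# readers


def read_point_variants(
    path, min_qual: float = 20.0, min_dp: int = 10
) -> List[PointVariant]:
    """Read single-nucleotide variants from a VCF, with quality filters.

    Records failing QUAL >= min_qual or INFO/DP >= min_dp are dropped;
    records with no DP while depth filtering is requested are skipped and
    counted in a log message.  A multi-allelic SNP line yields exactly one
    point variant (one mutated site, however many alternate alleles).
    """
    from cyvcf2 import VCF

    out: List[PointVariant] = []
    skipped_no_dp = 0
    for v in VCF(str(path)):
        if not v.is_snp:
            continue
        if min_qual is not None and (v.QUAL is None or v.QUAL < min_qual):
            continue
        if min_dp is not None and min_dp > 0:
            dp = v.INFO.get("DP")
            if dp is None:
                skipped_no_dp += 1
                continue
            if dp < min_dp:
                continue
        out.append(PointVariant(chrom=v.CHROM, pos=v.POS, id=v.ID))
    if skipped_no_dp:
        logger.warning("read_point_variants: skipped %d records lacking DP", skipped_no_dp)
    return out


def _first(value):
    """INFO fields declared Number=. come back as tuples; take the first."""
    if isinstance(value, (tuple, list, np.ndarray)):
        return value[0] if len(value) else None
    return value


def read_interval_variants(path) -> List[IntervalVariant]:
    """Read structural variants from a VCF with SVTYPE/END/SVLEN INFO fields.

    Span rules: [POS, END] when END is present; [POS, POS+|SVLEN|-1] for
    spanning classes (DEL/DUP/INV) without END; insertions and breakends are
    anchored at [POS, POS].  Spanning records with neither END nor SVLEN are
    skipped and counted in a log message.
    """
    from cyvcf2 import VCF

    out: List[IntervalVariant] = []
    skipped = 0
    for v in VCF(str(path)):
        svtype = v.INFO.get("SVTYPE")
        if svtype is None:
            continue
        svtype = str(svtype).upper()
        if svtype in ("BND", "TRA"):
            svtype = "TRA"
        elif svtype not in SVTYPES:
            svtype = "NA"
        pos = v.POS
        end = v.INFO.get("END")
        svlen = _first(v.INFO.get("SVLEN"))
        svlen = abs(int(svlen)) if svlen is not None else None
        if svtype == "INS":
            start, stop = pos, pos
            length = svlen if svlen else 1
        elif svtype == "TRA":
            start, stop = pos, pos
            length = 1
        else:  # spanning classes, plus NA treated as spanning when possible
            if end is not None:
                start, stop = pos, int(end)
            elif svlen:
                start, stop = pos, pos + svlen - 1
            else:
                skipped += 1
                continue
            length = stop - start + 1
        out.append(
            IntervalVariant(chrom=v.CHROM, start=start, end=stop, svtype=svtype,
                            length=max(length, 1), id=v.ID)
        )
    if skipped:
        logger.warning(
            "read_interval_variants: skipped %d spanning records with neither END nor SVLEN",
            skipped,
        )
    return out


def read_feature_intervals(path, feature: str = "exon") -> List[Tuple[str, int, int]]:
    """Read annotation intervals of one feature type from GFF3 or BED.

    Returns (chrom, start, end) tuples, 1-based inclusive, sorted per
    chromosome.  BED is read as 0-based half-open and normalized; BED rows
    have no feature type, so all rows are returned.  Format is chosen by
    extension (.bed / .gff, .gff3) or, failing that, by content sniffing.
    """
    import pyranges

    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".bed":
        fmt = "bed"
    elif suffix in (".gff", ".gff3"):
        fmt = "gff3"
    else:
        with open(p) as fh:
            head = fh.read(2048)
        if head.startswith("##gff-version") or head.count("\t") and len(
            head.splitlines()[0].split("\t")
        ) == 9:
            fmt = "gff3"
        elif head.strip():
            fmt = "bed"
        else:
            raise ValueError(f"cannot determine annotation format of {path}")
    if fmt == "bed":
        df = pyranges.read_bed(str(p), as_df=True)
    else:
        df = pyranges.read_gff3(str(p), as_df=True)
        if "Feature" in df.columns and feature is not None:
            df = df[df.Feature == feature]
    # pyranges is 0-based half-open internally for both formats
    out = [
        (str(c), int(s) + 1, int(e))
        for c, s, e in zip(df.Chromosome, df.Start, df.End)
    ]
    out.sort()
    return out


# ---------------------------------------------------------------------------
# sweep queries


class _ChromIndex:
    """Sorted-start index with running max-end, per chromosome."""

    def __init__(self, spans: Iterable[Tuple[str, int, int]]) -> None:
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in spans:
            by_chrom.setdefault(chrom, []).append((start, end))
        self.index: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            starts = np.array([s for s, _ in pairs], dtype=np.int64)
            ends = np.array([e for _, e in pairs], dtype=np.int64)
            self.index[chrom] = (starts, np.maximum.accumulate(ends))

    def contains_points(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Boolean mask: point i lies inside at least one indexed span."""
        out = np.zeros(len(positions), dtype=bool)
        chrom_arr = np.asarray(chroms, dtype=object)
        for chrom, (starts, maxends) in self.index.items():
            sel = np.flatnonzero(chrom_arr == chrom)
            if len(sel) == 0:
                continue
            pos = positions[sel]
            k = np.searchsorted(starts, pos, side="right")
            hit = np.zeros(len(pos), dtype=bool)
            nz = k > 0
            hit[nz] = maxends[k[nz] - 1] >= pos[nz]
            out[sel] = hit
        return out


def _merge_spans(spans: Iterable[Tuple[str, int, int]]) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Union of 1-based inclusive spans per chromosome, as sorted disjoint arrays."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end in spans:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        acc: List[List[int]] = []
        for s, e in pairs:
            if acc and s <= acc[-1][1] + 1:
                acc[-1][1] = max(acc[-1][1], e)
            else:
                acc.append([s, e])
        merged[chrom] = (
            np.array([a for a, _ in acc], dtype=np.int64),
            np.array([b for _, b in acc], dtype=np.int64),
        )
    return merged


def trapped_fraction(
    points: Sequence[PointVariant],
    intervals: Sequence[IntervalVariant],
    svtypes: Optional[Sequence[str]] = None,
) -> OverlapReport:
    """Count points lying within at least one interval's containment span.

    ``svtypes`` restricts which SV classes can trap (default: all, including
    1-nt insertion anchors).  Each point is counted once regardless of how
    many intervals contain it; trapped_fraction is 0 (flagged undefined)
    when there are no points.
    """
    if svtypes is not None:
        intervals = [iv for iv in intervals if iv.svtype in svtypes]
    idx = _ChromIndex((iv.chrom, iv.start, iv.end) for iv in intervals)
    n = len(points)
    if n:
        mask = idx.contains_points(
            [pt.chrom for pt in points], np.array([pt.pos for pt in points], dtype=np.int64)
        )
        trapped = int(mask.sum())
    else:
        trapped = 0
    return OverlapReport(
        total_points=n,
        trapped_points=trapped,
        trapped_fraction=(trapped / n) if n else 0.0,
        trapped_fraction_defined=n > 0,
    )


def feature_overlap_counts(
    points: Sequence[PointVariant],
    intervals: Sequence[IntervalVariant],
    features: Sequence[Tuple[str, int, int]],
) -> Tuple[int, int]:
    """(points inside >=1 feature, intervals overlapping >=1 feature by >=1 nt)."""
    idx = _ChromIndex(features)
    exonic_points = 0
    if points:
        mask = idx.contains_points(
            [pt.chrom for pt in points], np.array([pt.pos for pt in points], dtype=np.int64)
        )
        exonic_points = int(mask.sum())
    merged = _merge_spans(features)
    exonic_intervals = 0
    for iv in intervals:
        if iv.chrom not in merged:
            continue
        fstarts, fends = merged[iv.chrom]
        k = np.searchsorted(fstarts, iv.end, side="right")
        if k > 0 and fends[k - 1] >= iv.start:
            exonic_intervals += 1
    return exonic_points, exonic_intervals


def nucleotides_by_svtype(
    intervals: Sequence[IntervalVariant], merge_overlaps: bool = False
) -> Dict[str, int]:
    """Summed affected nucleotides per SV class.

    By default every call contributes its length (insertions contribute the
    inserted length, not the anchor).  With ``merge_overlaps`` spanning
    classes contribute the union of their spans instead.
    """
    totals: Dict[str, int] = {t: 0 for t in SVTYPES}
    if not merge_overlaps:
        for iv in intervals:
            totals[iv.svtype] += iv.length
        return {t: n for t, n in totals.items() if n}
    for svtype in SVTYPES:
        group = [iv for iv in intervals if iv.svtype == svtype]
        if not group:
            continue
        if svtype in _SPANNING:
            merged = _merge_spans((iv.chrom, iv.start, iv.end) for iv in group)
            totals[svtype] = int(
                sum((ends - starts + 1).sum() for starts, ends in merged.values())
            )
        else:
            totals[svtype] = sum(iv.length for iv in group)
    return {t: n for t, n in totals.items() if n}


def per_chromosome_sv_counts(intervals: Sequence[IntervalVariant]) -> pd.DataFrame:
    """Chromosome x svtype contingency table of SV counts."""
    if not intervals:
        return pd.DataFrame()
    df = pd.DataFrame(
        {"chrom": [iv.chrom for iv in intervals], "svtype": [iv.svtype for iv in intervals]}
    )
    return pd.crosstab(df.chrom, df.svtype)


def compute_overlap_report(
    points: Sequence[PointVariant],
    intervals: Sequence[IntervalVariant],
    features: Optional[Sequence[Tuple[str, int, int]]] = None,
    trap_svtypes: Optional[Sequence[str]] = None,
) -> OverlapReport:
    """Full overlap report: trapped stats, optional exonic stats, tallies."""
    report = trapped_fraction(points, intervals, svtypes=trap_svtypes)
    if features is not None:
        ep, ei = feature_overlap_counts(points, intervals, features)
        report.exonic_points = ep
        report.exonic_intervals = ei
    table = per_chromosome_sv_counts(intervals)
    report.per_chrom_by_type = {
        chrom: {t: int(c) for t, c in row.items() if c}
        for chrom, row in table.iterrows()
    } if len(table) else {}
    report.nt_by_type = nucleotides_by_svtype(intervals)
    return report


def write_overlap_report(report: OverlapReport, tsv_path, json_path=None) -> None:
    """Write the report as a key-value TSV and, optionally, as JSON."""
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"total_points\t{report.total_points}\n")
        fh.write(f"trapped_points\t{report.trapped_points}\n")
        frac = f"{report.trapped_fraction:.6f}" if report.trapped_fraction_defined else "."
        fh.write(f"trapped_fraction\t{frac}\n")
        fh.write(f"exonic_points\t{report.exonic_points if report.exonic_points is not None else '.'}\n")
        fh.write(
            f"exonic_intervals\t{report.exonic_intervals if report.exonic_intervals is not None else '.'}\n"
        )
        for svtype, nt in sorted(report.nt_by_type.items()):
            fh.write(f"nt_{svtype}\t{nt}\n")
        for chrom in sorted(report.per_chrom_by_type):
            for svtype, cnt in sorted(report.per_chrom_by_type[chrom].items()):
                fh.write(f"count_{chrom}_{svtype}\t{cnt}\n")
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# synthetic fixture generator

_VCF_SNP_HEADER = """\
##fileformat=VCFv4.2
##source=svload-synth
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

_VCF_SV_HEADER = """\
##fileformat=VCFv4.2
##source=svload-synth
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="Length of the variant">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INV,Description="Inversion">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic SNP/SV variant-file pair with known truth.

    ``svtype_mix`` gives sampling weights over SV classes; interval lengths
    (spans for spanning classes, inserted lengths for INS) are uniform on
    [min_sv_len, max_sv_len].
    """

    chromosomes: Dict[str, int]
    n_points: int = 100
    n_intervals: int = 20
    target_trapped_fraction: float = 0.5
    svtype_mix: Dict[str, float] = field(
        default_factory=lambda: {"DEL": 0.4, "INS": 0.2, "DUP": 0.2, "INV": 0.2}
    )
    min_sv_len: int = 50
    max_sv_len: int = 2000
    n_features: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise GenerationError("at least one chromosome required")
        if not 0.0 <= self.target_trapped_fraction <= 1.0:
            raise GenerationError("target_trapped_fraction must lie in [0, 1]")
        if any(l < 2 for l in self.chromosomes.values()):
            raise GenerationError("chromosome lengths must be >= 2")
        if self.min_sv_len < 1 or self.max_sv_len < self.min_sv_len:
            raise GenerationError("need 1 <= min_sv_len <= max_sv_len")
        bad = set(self.svtype_mix) - set(SVTYPES)
        if bad:
            raise GenerationError(f"unknown svtypes in mix: {sorted(bad)}")


def _contig_lines(chromosomes: Dict[str, int]) -> str:
    return "".join(
        f"##contig=<ID={c},length={l}>\n" for c, l in sorted(chromosomes.items())
    )


def synth_variant_pair(spec: SynthSpec, points_vcf, intervals_vcf, truth_json=None):
    """Generate a SNP VCF / SV VCF pair with an exactly known overlap truth.

    Exactly round(target_trapped_fraction * n_points) points are placed
    inside SV containment spans and the rest strictly outside all of them.
    Returns the truth record (also written to ``truth_json`` if given):
    the exact OverlapReport fields, plus the feature annotation written
    alongside when ``n_features > 0`` (features are random spans; exonic
    counts in the truth are computed by brute force on the generated data).

    Deterministic: identical specs yield byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    chroms = sorted(spec.chromosomes)
    lengths = np.array([spec.chromosomes[c] for c in chroms], dtype=np.int64)
    weights = lengths / lengths.sum()

    # --- intervals -------------------------------------------------------
    types = sorted(spec.svtype_mix)
    tw = np.array([spec.svtype_mix[t] for t in types], dtype=float)
    if tw.sum() <= 0:
        raise GenerationError("svtype_mix weights must sum to > 0")
    tw = tw / tw.sum()
    intervals: List[IntervalVariant] = []
    for i in range(spec.n_intervals):
        ci = int(rng.choice(len(chroms), p=weights))
        chrom, L = chroms[ci], int(lengths[ci])
        svtype = types[int(rng.choice(len(types), p=tw))]
        svlen = int(rng.integers(spec.min_sv_len, spec.max_sv_len + 1))
        if svtype in _SPANNING:
            span = min(svlen, L)
            start = int(rng.integers(1, L - span + 2))
            iv = IntervalVariant(chrom, start, start + span - 1, svtype, span, id=f"sv{i+1}")
        else:  # INS / TRA / NA anchored at 1 nt
            pos = int(rng.integers(1, L + 1))
            length = svlen if svtype == "INS" else 1
            iv = IntervalVariant(chrom, pos, pos, svtype, length, id=f"sv{i+1}")
        intervals.append(iv)

    # --- union of containment spans per chromosome -----------------------
    inside = _merge_spans((iv.chrom, iv.start, iv.end) for iv in intervals)
    inside_size = {c: int((e - s + 1).sum()) for c, (s, e) in inside.items()}
    total_inside = sum(inside_size.values())
    total_outside = int(lengths.sum()) - total_inside

    n_in = round(spec.target_trapped_fraction * spec.n_points)
    n_out = spec.n_points - n_in
    if n_in > 0 and total_inside == 0:
        raise GenerationError("no interval space to place trapped points")
    if n_out > 0 and total_outside == 0:
        raise GenerationError("intervals cover the genome; no outside space left")

    points: List[PointVariant] = []
    # inside points: uniform over the union of spans
    if n_in:
        span_chrom, span_start, span_end = [], [], []
        for c, (s, e) in inside.items():
            span_chrom += [c] * len(s)
            span_start += s.tolist()
            span_end += e.tolist()
        sizes = np.array(span_end, dtype=np.int64) - np.array(span_start, dtype=np.int64) + 1
        pick = rng.choice(len(sizes), size=n_in, p=sizes / sizes.sum())
        for j, si in enumerate(pick):
            pos = int(rng.integers(span_start[si], span_end[si] + 1))
            points.append(PointVariant(span_chrom[si], pos, id=f"snp_in{j+1}"))
    # outside points: rejection-sample positions in no span
    made = 0
    guard = 0
    while made < n_out:
        guard += 1
        if guard > 1000 * max(n_out, 1):
            raise GenerationError("could not place points outside intervals")
        ci = int(rng.choice(len(chroms), p=weights))
        chrom, L = chroms[ci], int(lengths[ci])
        pos = int(rng.integers(1, L + 1))
        if chrom in inside:
            s, e = inside[chrom]
            k = np.searchsorted(s, pos, side="right")
            if k > 0 and e[k - 1] >= pos:
                continue
        made += 1
        points.append(PointVariant(chrom, pos, id=f"snp_out{made}"))
    points.sort(key=lambda p: (p.chrom, p.pos))

    # --- optional features ----------------------------------------------
    features: Optional[List[Tuple[str, int, int]]] = None
    if spec.n_features:
        features = []
        for _ in range(spec.n_features):
            ci = int(rng.choice(len(chroms), p=weights))
            chrom, L = chroms[ci], int(lengths[ci])
            span = int(rng.integers(spec.min_sv_len, spec.max_sv_len + 1))
            span = min(span, L)
            start = int(rng.integers(1, L - span + 2))
            features.append((chrom, start, start + span - 1))
        features.sort()

    # --- write files ------------------------------------------------------
    contigs = _contig_lines(spec.chromosomes)
    with open(points_vcf, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_VCF_SNP_HEADER.format(contigs=contigs))
        for pt in points:
            fh.write(f"{pt.chrom}\t{pt.pos}\t{pt.id}\tA\tT\t60\tPASS\tDP=30\n")
    with open(intervals_vcf, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_VCF_SV_HEADER.format(contigs=contigs))
        for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.id or "")):
            info = f"SVTYPE={iv.svtype};DP=30"
            if iv.svtype in _SPANNING:
                info += f";END={iv.end};SVLEN={iv.end - iv.start + 1}"
            elif iv.svtype == "INS":
                info += f";SVLEN={iv.length}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.id}\tN\t<{iv.svtype}>\t60\tPASS\t{info}\n")

    # --- truth record (brute-force, independent of the sweep queries) ----
    trapped = 0
    for pt in points:
        if any(
            iv.chrom == pt.chrom and iv.start <= pt.pos <= iv.end for iv in intervals
        ):
            trapped += 1
    truth = {
        "total_points": spec.n_points,
        "trapped_points": trapped,
        "trapped_fraction": trapped / spec.n_points if spec.n_points else 0.0,
        "nt_by_type": nucleotides_by_svtype(intervals),
        "per_chrom_by_type": {
            c: {t: int(x) for t, x in row.items() if x}
            for c, row in per_chromosome_sv_counts(intervals).iterrows()
        },
        "n_intervals": spec.n_intervals,
    }
    assert trapped == n_in, "construction must place exactly the target count inside"
    if features is not None:
        ep = sum(
            1
            for pt in points
            if any(c == pt.chrom and s <= pt.pos <= e for c, s, e in features)
        )
        ei = sum(
            1
            for iv in intervals
            if any(c == iv.chrom and s <= iv.end and e >= iv.start for c, s, e in features)
        )
        truth["exonic_points"] = ep
        truth["exonic_intervals"] = ei
        bed = Path(str(points_vcf)).with_suffix(".features.bed")
        with open(bed, "w", encoding="utf-8", newline="\n") as fh:
            for c, s, e in features:
                fh.write(f"{c}\t{s - 1}\t{e}\tfeature\n")
        truth["features_bed"] = str(bed)
    if truth_json is not None:
        with open(truth_json, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return truth
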