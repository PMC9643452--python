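"""CpG sequence-context and domain annotation.

Every plus-strand CpG in a genome is annotated with its immediate flank
class (WCGW / SCGS / intermediate / ambiguous), its solo/social status
(distance to the nearest other CpG on the same contig), and its domain
membership (common PMD, HMD, or neither) plus a CpG-island flag and any
number of extra interval flags (e.g. histone marks).

The CpG dinucleotide is palindromic, so a single plus-strand record per
CG suffices; flank classes are symmetric under reverse complement
(W maps to W, S to S).

Coordinates are 0-based half-open throughout; ``pos`` is the position of
the C of the plus-strand ``CG``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WEAK = frozenset("AT")
STRONG = frozenset("CG")
_VALID_ALPHABET = frozenset("ACGTN")

DEFAULT_SOLO_THRESHOLD = 35


@dataclass
class GenomeSequence:
    """A single contig: name plus an uppercase A/C/G/T/N string."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.name!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.name!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[GenomeSequence]:
    """Load every contig of a (multi-)FASTA file."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return [GenomeSequence(name, str(fa[name][:])) for name in fa.keys()]


@dataclass
class IntervalSet:
    """Named set of 0-based half-open genomic intervals, merged on load."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for contig, start, end in self.intervals:
            if not start < end:
                raise ValueError(
                    f"interval set {self.name!r}: start must be < end, "
                    f"got {contig}:{start}-{end}"
                )
        self.intervals = merge_intervals(self.intervals)

    def _per_contig(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, tuple[list, list]] = {}
        for contig, start, end in self.intervals:
            out.setdefault(contig, ([], []))
            out[contig][0].append(start)
            out[contig][1].append(end)
        return {
            c: (np.asarray(s), np.asarray(e)) for c, (s, e) in out.items()
        }

    def contains(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership for an array of point positions."""
        positions = np.asarray(positions)
        per = self._per_contig().get(contig)
        if per is None:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = per
        # merged + sorted: a point is covered iff the nearest interval
        # starting at or before it extends past it
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(positions.shape, dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out


def merge_intervals(
    intervals: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Union overlapping/adjacent intervals per contig."""
    merged: list[tuple[str, int, int]] = []
    for contig in sorted({iv[0] for iv in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == contig)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((contig, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((contig, cur_s, cur_e))
    return merged


def read_bed(path, name: str | None = None) -> IntervalSet:
    """Read a BED3+ file into an IntervalSet.

    Raises ValueError naming the offending line number for malformed rows.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: malformed BED line {lineno}: "
                    f"expected >=3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}: malformed BED line {lineno}: "
                    f"non-integer coordinates"
                ) from None
            if start >= end:
                raise ValueError(
                    f"{path}: malformed BED line {lineno}: start >= end"
                )
            intervals.append((fields[0], start, end))
    return IntervalSet(name or str(path), intervals)


def find_cpgs(genome: GenomeSequence) -> np.ndarray:
    """Positions (of the C) of every plus-strand CG, ascending."""
    arr = np.frombuffer(genome.sequence.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def classify_flanks(genome: GenomeSequence, pos: int) -> str:
    """Flank class of the CpG whose C sits at ``pos``.

    WCGW: both immediate flanks (pos-1 and pos+2) are A/T; SCGS: both
    C/G; intermediate: one of each; ambiguous: a flank is N or falls off
    the contig edge.
    """
    seq = genome.sequence
    if not (0 <= pos and pos + 1 < len(seq) and seq[pos : pos + 2] == "CG"):
        raise ValueError(f"no CG at {genome.name}:{pos}")
    if pos - 1 < 0 or pos + 2 >= len(seq):
        return "ambiguous"
    left, right = seq[pos - 1], seq[pos + 2]
    if "N" in (left, right):
        return "ambiguous"
    if left in WEAK and right in WEAK:
        return "WCGW"
    if left in STRONG and right in STRONG:
        return "SCGS"
    return "intermediate"


def classify_solo(
    positions: np.ndarray, threshold: int = DEFAULT_SOLO_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Solo flags and nearest-CpG distances for sorted positions of one contig.

    Distance is start-to-start between the C positions. A CpG is solo iff
    its nearest neighbour is at least ``threshold`` bp away; the only CpG
    on a contig has distance +inf and is solo.
    """
    positions = np.asarray(positions)
    n = len(positions)
    if n == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if n == 1:
        return np.ones(1, dtype=bool), np.full(1, np.inf)
    gaps = np.diff(positions).astype(float)
    nearest = np.empty(n)
    nearest[0] = gaps[0]
    nearest[-1] = gaps[-1]
    if n > 2:
        nearest[1:-1] = np.minimum(gaps[:-1], gaps[1:])
    return nearest >= threshold, nearest


def annotate(
    genomes: GenomeSequence | list[GenomeSequence],
    pmd: IntervalSet | None = None,
    hmd: IntervalSet | None = None,
    cgi: IntervalSet | None = None,
    extra: dict[str, IntervalSet] | None = None,
    solo_threshold: int = DEFAULT_SOLO_THRESHOLD,
) -> pd.DataFrame:
    """Full per-CpG annotation table.

    Columns: contig, pos (0-based C position), flank_class, solo,
    nearest_cpg_distance, domain (commonPMD / HMD / neither, mutually
    exclusive with PMD taking precedence), in_cgi, plus one boolean
    column per extra interval set.

    Interval sets naming contigs absent from the genome trigger a warning
    and are skipped for those contigs.
    """
    if isinstance(genomes, GenomeSequence):
        genomes = [genomes]
    extra = extra or {}
    contig_names = {g.name for g in genomes}
    for iset in filter(None, [pmd, hmd, cgi, *extra.values()]):
        unknown = {iv[0] for iv in iset.intervals} - contig_names
        if unknown:
            warnings.warn(
                f"interval set {iset.name!r}: skipping unknown contigs "
                f"{sorted(unknown)}",
                stacklevel=2,
            )

    frames = []
    for genome in genomes:
        pos = find_cpgs(genome)
        solo, nearest = classify_solo(pos, solo_threshold)
        flank = [classify_flanks(genome, int(p)) for p in pos]
        in_pmd = (
            pmd.contains(genome.name, pos)
            if pmd is not None
            else np.zeros(len(pos), dtype=bool)
        )
        in_hmd = (
            hmd.contains(genome.name, pos)
            if hmd is not None
            else np.zeros(len(pos), dtype=bool)
        )
        domain = np.where(in_pmd, "commonPMD", np.where(in_hmd, "HMD", "neither"))
        rec = {
            "contig": genome.name,
            "pos": pos,
            "flank_class": flank,
            "solo": solo,
            "nearest_cpg_distance": nearest,
            "domain": domain,
            "in_cgi": (
                cgi.contains(genome.name, pos)
                if cgi is not None
                else np.zeros(len(pos), dtype=bool)
            ),
        }
        for name, iset in extra.items():
            rec[name] = iset.contains(genome.name, pos)
        frames.append(pd.DataFrame(rec))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return out


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
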