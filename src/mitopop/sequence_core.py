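"""Aligned sequence handling.

Reading and validation of aligned FASTA, the missing-data site filter,
haplotype collapsing, pairwise difference counting with pairwise deletion,
and nearest-reference haplogroup assignment.

Coordinates are 0-based internally; reports print 1-based positions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

# '-', 'N' and every non-ACGT IUPAC code count as missing/ambiguous, both
# for the site filter and for pairwise deletion.
VALID_CHARS = set("ACGTRYSWKMBDHVN-")
_BASES = "ACGT"
MISSING_CODE = 255

_ENCODE = np.full(256, MISSING_CODE, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i

REGIONS = ("Highland", "Lowland_east", "Lowland_west")


class AlignmentError(ValueError):
    """Raised for malformed alignment input."""


@dataclass
class Alignment:
    """A rectangular haploid alignment with site-filter provenance.

    ``kept_site_indices`` maps current columns back to the coordinates of
    the originally loaded alignment (0-based, strictly increasing).
    """

    sample_ids: list[str]
    seqs: list[str]
    kept_site_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        if len(self.seqs) < 1:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError("unaligned input: ragged sequence lengths")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("duplicate id")
        self.seqs = [s.upper() for s in self.seqs]
        bad = set("".join(self.seqs)) - VALID_CHARS
        if bad:
            raise AlignmentError(f"bad symbol: {sorted(bad)!r}")
        if self.kept_site_indices is None:
            self.kept_site_indices = np.arange(self.L)
        self.kept_site_indices = np.asarray(self.kept_site_indices, dtype=int)
        if self.kept_site_indices.shape != (self.L,) or (
            self.L > 1 and not np.all(np.diff(self.kept_site_indices) > 0)
        ):
            raise AlignmentError("kept_site_indices must be strictly increasing, one per site")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    def codes(self) -> np.ndarray:
        """(n, L) uint8 matrix; A,C,G,T -> 0..3, anything else -> 255."""
        flat = np.frombuffer("".join(self.seqs).encode("ascii"), dtype=np.uint8)
        return _ENCODE[flat].reshape(self.n, self.L)

    def subset(self, ids: list[str]) -> "Alignment":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing}")
        return Alignment(
            sample_ids=list(ids),
            seqs=[self.seqs[index[s]] for s in ids],
            kept_site_indices=self.kept_site_indices.copy(),
        )

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.sample_ids, self.seqs):
                fh.write(f">{sid}\n{seq}\n")


@dataclass
class HaplotypeTable:
    """Distinct sequences on retained sites, with counts and members."""

    haplotype_ids: list[str]
    seqs: list[str]
    counts: np.ndarray
    members: list[list[str]]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.seqs)

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype_id": self.haplotype_ids,
                "count": self.counts,
                "members": [",".join(m) for m in self.members],
            }
        )


@dataclass
class PairwiseDiffs:
    """Nucleotide difference counts and comparable-site counts per pair."""

    diffs: np.ndarray  # (n, n) int
    comparable: np.ndarray  # (n, n) int

    @property
    def n(self) -> int:
        return self.diffs.shape[0]

    def per_site(self) -> np.ndarray:
        """p-distance matrix (differences / comparable sites), 0 diagonal."""
        out = np.zeros_like(self.diffs, dtype=float)
        mask = ~np.eye(self.n, dtype=bool)
        out[mask] = self.diffs[mask] / self.comparable[mask]
        return out


@dataclass
class FilterReport:
    n_sites_before: int
    n_sites_after: int
    removed_original_coords: np.ndarray  # 0-based original coordinates

    def removed_positions_1based(self) -> list[int]:
        return [int(i) + 1 for i in self.removed_original_coords]


def read_alignment(fasta_path: str | Path | io.TextIOBase) -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment`.

    Sequences are uppercased. Raises :class:`AlignmentError` on ragged
    lengths ("unaligned input"), duplicate ids or illegal characters.
    """
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if not records:
        raise AlignmentError("empty alignment: no FASTA records")
    return Alignment(
        sample_ids=[r.id for r in records],
        seqs=[str(r.seq) for r in records],
    )


def filter_sites(
    aln: Alignment, max_missing_frac: float = 0.70
) -> tuple[Alignment, FilterReport]:
    """Drop sites where the missing/ambiguous fraction strictly exceeds
    ``max_missing_frac`` (a site at exactly the threshold is kept)."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    codes = aln.codes()
    missing_frac = (codes == MISSING_CODE).mean(axis=0)
    keep = missing_frac <= max_missing_frac
    if not keep.any():
        raise AlignmentError("empty alignment: all sites removed by filter")
    kept_idx = np.flatnonzero(keep)
    report = FilterReport(
        n_sites_before=aln.L,
        n_sites_after=int(keep.sum()),
        removed_original_coords=aln.kept_site_indices[~keep],
    )
    filtered = Alignment(
        sample_ids=list(aln.sample_ids),
        seqs=["".join(s[i] for i in kept_idx) for s in aln.seqs],
        kept_site_indices=aln.kept_site_indices[keep],
    )
    return filtered, report


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Group sequences identical on all retained sites (exact string match)."""
    order: dict[str, int] = {}
    members: list[list[str]] = []
    for sid, seq in zip(aln.sample_ids, aln.seqs):
        if seq not in order:
            order[seq] = len(members)
            members.append([])
        members[order[seq]].append(sid)
    seqs = list(order.keys())
    width = max(2, len(str(len(seqs))))
    return HaplotypeTable(
        haplotype_ids=[f"Hap_{i + 1:0{width}d}" for i in range(len(seqs))],
        seqs=seqs,
        counts=np.array([len(m) for m in members], dtype=int),
        members=members,
    )


def pairwise_differences(aln: Alignment) -> PairwiseDiffs:
    """Count pairwise nucleotide differences with pairwise deletion.

    Sites where either sequence carries a missing/ambiguous symbol are
    excluded from that pair's comparison.
    """
    if aln.n < 2:
        raise ValueError("need at least 2 sequences")
    codes = aln.codes()
    valid = (codes != MISSING_CODE).astype(np.int64)
    comparable = valid @ valid.T
    matches = np.zeros_like(comparable)
    for b in range(4):
        xb = (codes == b).astype(np.int64)
        matches += xb @ xb.T
    diffs = comparable - matches
    off = ~np.eye(aln.n, dtype=bool)
    if np.any(comparable[off] == 0):
        i, j = np.argwhere((comparable == 0) & off)[0]
        raise AlignmentError(
            f"incomparable pair: {aln.sample_ids[i]} vs {aln.sample_ids[j]} share no sites"
        )
    return PairwiseDiffs(diffs=diffs, comparable=comparable)


def _pair_diff(a: str, b: str) -> tuple[int, int]:
    d = comp = 0
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            comp += 1
            if x != y:
                d += 1
    return d, comp


def assign_haplogroup(
    query_seq: str, reference_panel: dict[str, str] | list[tuple[str, str]]
) -> tuple[list[str], int]:
    """Label a query by its minimum-difference reference haplotype.

    ``reference_panel`` maps label -> aligned reference sequence (same frame
    as the query). Returns ``(labels, distance)`` where ``labels`` lists all
    tied minimum-distance labels (singleton list when unique).
    """
    panel = list(reference_panel.items()) if isinstance(reference_panel, dict) else list(reference_panel)
    if not panel:
        raise ValueError("empty reference panel")
    query_seq = query_seq.upper()
    best: dict[str, int] = {}
    for label, ref in panel:
        if len(ref) != len(query_seq):
            raise AlignmentError("unaligned input: panel frame differs from query")
        d, comp = _pair_diff(query_seq, ref.upper())
        if comp == 0:
            raise AlignmentError(f"incomparable pair: query vs reference {label}")
        if label not in best or d < best[label]:
            best[label] = d
    dmin = min(best.values())
    labels = sorted(lab for lab, d in best.items() if d == dmin)
    return labels, int(dmin)


def read_sample_table(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read sample metadata (TSV or CSV, sniffed from the header line).

    Required columns: sample_id, locality, region, elevation, population.
    With ``validate=True`` enforces the elevation rule: region is Highland
    iff elevation > 1000 m.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    required = {"sample_id", "locality", "region", "elevation", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate id in metadata")
    if validate:
        high = df["elevation"] > 1000
        bad = (df["region"] == "Highland") != high
        if bad.any():
            offenders = df.loc[bad, "sample_id"].tolist()
            raise ValueError(
                f"region/elevation mismatch (Highland iff >1000 m): {offenders}"
            )
    return df


def check_metadata_covers(aln: Alignment, meta: pd.DataFrame) -> None:
    missing = set(aln.sample_ids) - set(meta["sample_id"])
    if missing:
        raise ValueError(f"metadata missing alignment ids: {sorted(missing)}")
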