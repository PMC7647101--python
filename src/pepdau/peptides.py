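"""Anchored peptide parsing, window extraction and table cleaning.

The analysis operates on a :class:`PeptideSet`: equal-length sequence windows
aligned on an anchoring residue (a phosphosite, a protease P1 position, a
mature N-terminus...).  Input peptides arrive either pre-aligned, or as raw
sequences carrying one of three anchor annotations:

* a lowercase letter inside the sequence — ``ASTRSkSSTD`` anchors on the K;
* an uppercase letter followed by ``*`` — ``ASTRSK*SSTD``, same anchor;
* a positional token ``K123`` naming the residue and its 1-based position in
  the full protein.

Windows are cut from full-length proteins with ``upstream`` residues before
and ``downstream`` after the anchor; columns that fall outside the protein
are padded with ``X``, which every statistic ignores.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .proteome import PAD, STANDARD_AA, Proteome

_STANDARD = frozenset(STANDARD_AA)
_POSITIONAL = re.compile(r"^([A-Za-z])(\d+)$")


class PeptideError(ValueError):
    """Raised for malformed peptide input."""


@dataclass
class AnchoredPeptide:
    """A peptide (or full protein) with a located anchoring residue.

    ``anchor_index`` is 1-based within ``clean_sequence``.  When
    ``positional`` is true, ``clean_sequence`` is the full protein and the
    index is a protein coordinate; otherwise the peptide must be located in
    its parent protein before windows can be extracted.
    """

    protein_id: str
    clean_sequence: str
    anchor_index: int
    positional: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.anchor_index <= len(self.clean_sequence):
            raise PeptideError(
                f"anchor index {self.anchor_index} outside sequence of length "
                f"{len(self.clean_sequence)} ({self.protein_id})"
            )

    @property
    def anchor_residue(self) -> str:
        return self.clean_sequence[self.anchor_index - 1]


@dataclass
class PeptideSet:
    """Equal-length windows aligned on an anchor column.

    Invariants: every window has length ``upstream + 1 + downstream``; the
    anchor sits at 0-based column ``upstream``; ``X`` occurs only as a
    contiguous prefix and/or suffix (terminal padding), never interior.
    """

    windows: list[str]
    upstream: int
    downstream: int
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        L = self.upstream + 1 + self.downstream
        bad = [w for w in self.windows if len(w) != L]
        if bad:
            raise PeptideError(
                f"{len(bad)} window(s) do not have length {L}: "
                f"e.g. {bad[0]!r}"
            )
        for w in self.windows:
            core = w.strip(PAD)
            if PAD in core:
                raise PeptideError(f"interior padding X in window {w!r}")
            if not core:
                raise PeptideError(f"window {w!r} is all padding")
        if self.source_ids and len(self.source_ids) != len(self.windows):
            raise PeptideError("source_ids length does not match windows")

    @property
    def L(self) -> int:
        return self.upstream + 1 + self.downstream

    @property
    def anchor_column(self) -> int:
        return self.upstream

    def __len__(self) -> int:
        return len(self.windows)

    def column_labels(self, style: str = "offset") -> list[str]:
        """Column labels: ``offset`` gives -u..0..+d, ``protease`` gives
        P{u}..P1, P1'..P{d+1}' (anchor = P1, scissile bond after it)."""
        if style == "offset":
            return [str(i - self.upstream) for i in range(self.L)]
        if style == "protease":
            left = [f"P{self.upstream + 1 - i}" for i in range(self.upstream)]
            right = [f"P{i}'" for i in range(1, self.downstream + 1)]
            return left + ["P1"] + right
        raise ValueError(f"unknown label style {style!r}")


def parse_anchored_sequence(raw: str) -> tuple[str, list[int]]:
    """Locate anchor marks in a raw peptide string.

    Returns the upper-cased sequence with asterisks removed, and the 1-based
    indices of every anchor (lowercase letters and ``*``-flagged letters).
    """
    if not raw:
        raise PeptideError("empty peptide string")
    if not re.fullmatch(r"[A-Za-z*]+", raw):
        raise PeptideError(f"peptide {raw!r} contains non-letter characters")
    if raw[0] == "*":
        raise PeptideError(f"asterisk cannot start a peptide: {raw!r}")
    clean: list[str] = []
    anchors: list[int] = []
    for ch in raw:
        if ch == "*":
            if anchors and anchors[-1] == len(clean):
                continue  # "k*" marks the same residue twice
            anchors.append(len(clean))
        else:
            clean.append(ch.upper())
            if ch.islower():
                anchors.append(len(clean))
    letters = [c for c in raw if c != "*"]
    if letters and all(c.islower() for c in letters):
        raise PeptideError(
            f"peptide {raw!r} is entirely lowercase; anchors are ambiguous"
        )
    anchors = sorted(set(anchors))
    if not anchors:
        raise PeptideError(f"no anchor mark (lowercase or '*') in {raw!r}")
    return "".join(clean), anchors


def resolve_position_anchor(
    token: str, proteome: Proteome, protein_id: str
) -> AnchoredPeptide:
    """Resolve a positional anchor token like ``K123`` against a protein.

    The residue at the stated 1-based position must match the token's letter.
    """
    m = _POSITIONAL.match(token)
    if not m:
        raise PeptideError(f"malformed positional anchor {token!r}")
    aa, pos = m.group(1).upper(), int(m.group(2))
    seq = proteome.sequence(protein_id)
    if not 1 <= pos <= len(seq):
        raise PeptideError(
            f"anchor {token!r} out of range for {protein_id!r} "
            f"(length {len(seq)})"
        )
    found = seq[pos - 1]
    if found != aa:
        raise PeptideError(
            f"anchor {token!r} mismatch in {protein_id!r}: expected {aa}, "
            f"found {found} at position {pos}"
        )
    return AnchoredPeptide(protein_id, seq, pos, positional=True)


def _protein_anchor_position(anchor: AnchoredPeptide, proteome: Proteome) -> int:
    """1-based anchor position within the full protein sequence."""
    if anchor.positional:
        return anchor.anchor_index
    seq = proteome.sequence(anchor.protein_id)
    at = seq.find(anchor.clean_sequence)
    if at < 0:
        raise PeptideError(
            f"peptide {anchor.clean_sequence!r} not found in protein "
            f"{anchor.protein_id!r}"
        )
    return at + anchor.anchor_index


def extract_window(seq: str, anchor_pos: int, upstream: int, downstream: int) -> str:
    """Cut ``seq[anchor-upstream : anchor+downstream]`` (1-based anchor),
    padding out-of-range columns with X."""
    start = anchor_pos - 1 - upstream
    end = anchor_pos + downstream
    left = max(0, -start)
    right = max(0, end - len(seq))
    return PAD * left + seq[max(0, start) : min(len(seq), end)] + PAD * right


def extract_windows(
    proteome: Proteome,
    anchors: list[AnchoredPeptide],
    upstream: int,
    downstream: int,
) -> PeptideSet:
    """Extract equal-length windows around each anchor from the full proteins.

    Anchors on non-standard residues are rejected: the anchor must be a
    testable amino acid.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream offsets must be >= 0")
    missing = sorted(
        {a.protein_id for a in anchors if a.protein_id not in proteome}
    )
    if missing:
        raise PeptideError(
            f"{len(missing)} anchor protein id(s) absent from proteome: "
            f"{missing[:10]}"
        )
    windows: list[str] = []
    ids: list[str] = []
    for a in anchors:
        seq = proteome.sequence(a.protein_id)
        pos = _protein_anchor_position(a, proteome)
        res = seq[pos - 1]
        if res not in _STANDARD:
            raise PeptideError(
                f"anchor at {a.protein_id}:{pos} is non-standard residue "
                f"{res!r}"
            )
        windows.append(extract_window(seq, pos, upstream, downstream))
        ids.append(a.protein_id)
    return PeptideSet(windows, upstream, downstream, source_ids=ids)


def format_aligned(
    sequences: list[str],
    anchor_column: int,
    source_ids: list[str] | None = None,
) -> PeptideSet:
    """Build a :class:`PeptideSet` from pre-aligned equal-length sequences."""
    if not sequences:
        raise PeptideError("no sequences supplied")
    L = len(sequences[0])
    ragged = [
        (i, s) for i, s in enumerate(sequences) if len(s) != L
    ]
    if ragged:
        rows = ", ".join(f"row {i} ({s!r})" for i, s in ragged[:5])
        raise PeptideError(f"sequences are not equal length: {rows}")
    if not 0 <= anchor_column < L:
        raise PeptideError(
            f"anchor column {anchor_column} outside window of length {L}"
        )
    seqs = [s.upper() for s in sequences]
    allowed = _STANDARD | {PAD}
    for s in seqs:
        bad = set(s) - allowed
        if bad:
            raise PeptideError(
                f"sequence {s!r} contains unsupported symbols {sorted(bad)}"
            )
    return PeptideSet(
        seqs, anchor_column, L - 1 - anchor_column,
        source_ids=list(source_ids or []),
    )


def clean_peptides(
    rows: pd.DataFrame | list[tuple[str, str]],
    anchor_AAs: set[str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Clean a raw (protein_id, peptide) table before fetching windows.

    Drops rows whose peptide carries no anchor mark on a residue in
    ``anchor_AAs``, collapses exact duplicate rows, and expands a peptide
    with k usable anchors into k single-anchor rows (lowercase at the
    anchor).  Returns the cleaned table and a report of counts.
    """
    if not anchor_AAs:
        raise ValueError("anchor_AAs must be non-empty")
    anchor_AAs = {a.upper() for a in anchor_AAs}
    if isinstance(rows, pd.DataFrame):
        pairs = list(zip(rows.iloc[:, 0].astype(str), rows.iloc[:, 1].astype(str)))
    else:
        pairs = [(str(p), str(s)) for p, s in rows]
    n_in = len(pairs)
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    dropped = 0
    expanded = 0
    for pid, raw in pairs:
        if (pid, raw) in seen:
            continue
        seen.add((pid, raw))
        try:
            clean, anchors = parse_anchored_sequence(raw)
        except PeptideError:
            dropped += 1
            continue
        usable = [i for i in anchors if clean[i - 1] in anchor_AAs]
        if not usable:
            dropped += 1
            continue
        if len(usable) > 1:
            expanded += len(usable) - 1
        for i in usable:
            annotated = clean[: i - 1] + clean[i - 1].lower() + clean[i:]
            out.append((pid, annotated))
    if not out:
        raise PeptideError("no usable peptides after cleaning")
    report = {
        "input": n_in,
        "deduplicated": n_in - len(seen),
        "dropped": dropped,
        "expanded": expanded,
        "kept": len(out),
    }
    return pd.DataFrame(out, columns=["protein_id", "peptide"]), report


def read_peptide_tsv(path) -> pd.DataFrame:
    """Read a peptide table: TSV with columns ``protein_id`` and either
    ``peptide`` (anchored syntax) or ``site`` (positional syntax)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "protein_id" not in df.columns:
        raise PeptideError(
            f"{path}: expected a 'protein_id' column, got {list(df.columns)}"
        )
    if "peptide" not in df.columns and "site" not in df.columns:
        raise PeptideError(
            f"{path}: expected a 'peptide' or 'site' column, got "
            f"{list(df.columns)}"
        )
    return df
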