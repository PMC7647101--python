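"""Proteome container and FASTA I/O.

A :class:`Proteome` is the universe from which anchored peptide windows and
background subsequences are drawn.  Sequences are stored upper-cased over the
20 standard amino acids plus the non-standard symbols ``X U B Z *`` that occur
in UniProt FASTA releases; non-standard symbols are kept on ingest (dropping
whole proteins would bias background frequencies) but every downstream
statistic treats them as non-countable, exactly like window padding.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

#: The 20 standard amino acids, alphabetically.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Padding symbol for window columns beyond a protein's termini.
PAD = "X"

#: Symbols tolerated in input sequences but excluded from all statistics.
NON_COUNTABLE = frozenset("XUBZ*")

_ALLOWED = frozenset(STANDARD_AA) | NON_COUNTABLE

#: Residues after which the initiator methionine is cleaved co-translationally.
MET_CLEAVAGE_SET = frozenset("GASTCPV")

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|]+)\|")


class ProteomeError(ValueError):
    """Raised for malformed proteome input."""


@dataclass
class Proteome:
    """An identified collection of full-length protein sequences.

    Parameters
    ----------
    records
        ``(protein_id, sequence)`` pairs; IDs unique, sequences non-empty
        and upper-case.
    species
        Free-text species tag carried through to results metadata.
    source
        File path or tag describing where the sequences came from.
    """

    records: list[tuple[str, str]]
    species: str = "unknown"
    source: str = ""
    #: UniProt accession -> primary id aliases (``sp|ACC|NAME`` headers).
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, seq in self.records:
            if pid in seen:
                raise ProteomeError(f"duplicate protein id: {pid!r}")
            seen.add(pid)
            if not seq:
                raise ProteomeError(f"empty sequence for protein {pid!r}")
            if seq != seq.upper():
                raise ProteomeError(f"sequence for {pid!r} is not upper-case")
        self._index = {pid: seq for pid, seq in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index or protein_id in self.aliases

    def sequence(self, protein_id: str) -> str:
        """Return the sequence for ``protein_id`` (accession aliases accepted)."""
        try:
            return self._index[protein_id]
        except KeyError:
            pass
        try:
            return self._index[self.aliases[protein_id]]
        except KeyError:
            raise KeyError(f"protein id not in proteome: {protein_id!r}") from None

    def ids(self) -> list[str]:
        return [pid for pid, _ in self.records]

    def subset(self, protein_ids, complement: bool = False) -> "Proteome":
        """Restrict to ``protein_ids`` (or to everything else)."""
        wanted = {self.aliases.get(p, p) for p in protein_ids}
        kept = [
            (pid, seq)
            for pid, seq in self.records
            if (pid in wanted) != complement
        ]
        if not kept:
            raise ProteomeError(
                "proteome subset is empty "
                f"({'complement of' if complement else 'selection of'} "
                f"{len(wanted)} ids)"
            )
        aliases = {a: p for a, p in self.aliases.items() if p in dict(kept)}
        return Proteome(kept, species=self.species, source=self.source,
                        aliases=aliases)


def _validate_alphabet(pid: str, seq: str) -> None:
    bad = set(seq) - _ALLOWED
    if bad:
        raise ProteomeError(
            f"protein {pid!r} contains unsupported symbols: {sorted(bad)}"
        )


def read_fasta(path, species: str = "unknown") -> Proteome:
    """Read a protein FASTA file into a :class:`Proteome`.

    The protein id is the header token up to the first whitespace; for
    UniProt-style ``sp|ACC|NAME`` headers the accession is additionally
    registered as an alias.  Sequences are upper-cased and line wraps joined.
    """
    records: list[tuple[str, str]] = []
    aliases: dict[str, str] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ProteomeError(f"duplicate protein id in {path}: {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if not seq:
            raise ProteomeError(f"empty sequence for protein {pid!r} in {path}")
        _validate_alphabet(pid, seq)
        m = _UNIPROT_HEADER.match(pid)
        if m and m.group(1) != pid:
            aliases[m.group(1)] = pid
        records.append((pid, seq))
    if not records:
        raise ProteomeError(f"no FASTA records found in {path}")
    return Proteome(records, species=species, source=str(path), aliases=aliases)


def write_fasta(proteome: Proteome, path, width: int = 60) -> None:
    """Write a proteome back to FASTA (fixed line width)."""
    with open(path, "w") as fh:
        for pid, seq in proteome.records:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def cleave_initiator_met(proteome: Proteome, mode: str = "all") -> Proteome:
    """Remove the initiator methionine from protein N-termini.

    ``mode="all"`` strips a leading M from every sequence — the preprocessing
    used when the downstream analysis concerns mature N-termini regardless of
    processing rule (e.g. N-terminal acetylation studies).  ``mode="biological"``
    strips the leading M only when the second residue is one of
    ``G A S T C P V``, the residues after which methionine aminopeptidases act
    co-translationally.

    Sequences that become empty are dropped; a warning reports how many.
    """
    if mode not in ("all", "biological"):
        raise ValueError(f"mode must be 'all' or 'biological', got {mode!r}")
    out: list[tuple[str, str]] = []
    dropped = 0
    for pid, seq in proteome.records:
        if seq.startswith("M") and (
            mode == "all" or (len(seq) > 1 and seq[1] in MET_CLEAVAGE_SET)
        ):
            seq = seq[1:]
        if seq:
            out.append((pid, seq))
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"cleave_initiator_met dropped {dropped} sequence(s) that became "
            "empty", stacklevel=2,
        )
    if not out:
        raise ProteomeError("all sequences became empty after Met removal")
    aliases = {a: p for a, p in proteome.aliases.items() if p in dict(out)}
    return Proteome(out, species=proteome.species,
                    source=proteome.source, aliases=aliases)
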