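"""Scan static structures for alternating alpha_R/alpha_L motifs.

The motif of interest is a window of residues whose quadrant labels follow
a strictly alternating helical pattern (for example aR-aL-aR), optionally
constrained to a residue-name sequence such as Thr-Gly-Val.  Because the
labels are internal coordinates, hits are invariant under rigid-body
motion of the structure.  Multi-chain structures are scanned per chain and
windows never span residue-numbering gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .dihedral_analysis import DihedralPair, Label, assign_phi_psi, classify
from .trajectory_io import Frame, ParseError, TopologyError, read_multimodel_pdb

DEFAULT_PATTERN: tuple[Label, ...] = (Label.ALPHA_R, Label.ALPHA_L, Label.ALPHA_R)


@dataclass(frozen=True)
class MotifHit:
    """One window matching the label pattern (and sequence constraint)."""

    structure_id: str
    chain: str
    start_residue: int
    residue_names: tuple[str, ...]
    labels: tuple[Label, ...]
    phi_psi: tuple[DihedralPair, ...]


def _normalize_pattern(pattern: Sequence[Label | str]) -> tuple[Label, ...]:
    out = []
    for item in pattern:
        if isinstance(item, Label):
            out.append(item)
        else:
            key = str(item).strip().upper()
            alias = {"R": "ALPHA_R", "L": "ALPHA_L", "AR": "ALPHA_R", "AL": "ALPHA_L"}
            out.append(Label[alias.get(key, key)])
    if len(out) < 3:
        raise ValueError("motif pattern must have length >= 3")
    for a, b in zip(out, out[1:]):
        if a == b or a not in (Label.ALPHA_R, Label.ALPHA_L):
            raise ValueError("motif pattern must strictly alternate ALPHA_R/ALPHA_L")
    if out[-1] not in (Label.ALPHA_R, Label.ALPHA_L):
        raise ValueError("motif pattern must strictly alternate ALPHA_R/ALPHA_L")
    return tuple(out)


def scan_structure(
    structure: Frame,
    sequence_constraint: Sequence[str] | None = None,
    pattern: Sequence[Label | str] = DEFAULT_PATTERN,
    chain: str | None = None,
    structure_id: str = "",
) -> list[MotifHit]:
    """All windows whose labels equal ``pattern``.

    Overlapping hits are all reported.  When ``sequence_constraint`` is
    given the window's residue names must also match it (case-insensitive
    3-letter codes).  ``chain=None`` scans every chain in the structure.
    """
    pattern = _normalize_pattern(pattern)
    if sequence_constraint is not None:
        constraint = tuple(s.upper() for s in sequence_constraint)
        if len(constraint) != len(pattern):
            raise ValueError("sequence constraint must match the pattern length")
    else:
        constraint = None

    chains = (
        [chain]
        if chain is not None
        else sorted({a.chain_id for a in structure.atoms})
    )
    hits: list[MotifHit] = []
    for ch in chains:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pairs = assign_phi_psi(structure, ch)
        names: dict[int, str] = {}
        for atom in structure.atoms:
            if atom.chain_id == ch:
                names.setdefault(atom.residue_seq, atom.residue_name)
        seqs = sorted(pairs)
        k = len(pattern)
        for start in range(len(seqs) - k + 1):
            window = seqs[start : start + k]
            if any(b - a != 1 for a, b in zip(window, window[1:])):
                continue  # numbering gap breaks the window
            labels = tuple(classify(pairs[s]) for s in window)
            if labels != pattern:
                continue
            window_names = tuple(names.get(s, "").upper() for s in window)
            if constraint is not None and window_names != constraint:
                continue
            hits.append(
                MotifHit(
                    structure_id=structure_id,
                    chain=ch,
                    start_residue=window[0],
                    residue_names=window_names,
                    labels=labels,
                    phi_psi=tuple(pairs[s] for s in window),
                )
            )
    return hits


@dataclass
class DirectoryScanSummary:
    """Corpus-level totals of a motif scan over structure files."""

    n_structures: int
    n_structures_with_hits: int
    total_hits: int
    hits_by_structure: dict[str, list[MotifHit]] = field(default_factory=dict)


def scan_directory(
    directory,
    sequence_constraint: Sequence[str] | None = None,
    pattern: Sequence[Label | str] = DEFAULT_PATTERN,
    chain: str | None = None,
    glob: str = "*.pdb",
) -> DirectoryScanSummary:
    """Scan every structure file in a directory; skip unparseable files.

    The first model of each file is scanned.  Files that fail to parse
    are reported with a warning and skipped rather than aborting the
    corpus scan.  An empty directory gives an empty summary.
    """
    directory = Path(directory)
    hits_by_structure: dict[str, list[MotifHit]] = {}
    n_structures = 0
    for path in sorted(directory.glob(glob)):
        try:
            traj = read_multimodel_pdb(path)
        except (ParseError, TopologyError, OSError) as exc:
            warnings.warn(f"skipping {path.name}: {exc}", stacklevel=2)
            continue
        n_structures += 1
        hits = scan_structure(
            traj.frames[0],
            sequence_constraint=sequence_constraint,
            pattern=pattern,
            chain=chain,
            structure_id=path.stem,
        )
        if hits:
            hits_by_structure[path.stem] = hits
    return DirectoryScanSummary(
        n_structures=n_structures,
        n_structures_with_hits=len(hits_by_structure),
        total_hits=sum(len(h) for h in hits_by_structure.values()),
        hits_by_structure=hits_by_structure,
    )
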