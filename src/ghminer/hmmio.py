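"""Profile-HMM container and HMMER3 ASCII text I/O (subset).

A :class:`ProfileHMM` holds the match/insert emission probabilities and the
core-state transition probabilities of one protein domain model, on the
20-letter amino-acid alphabet in HMMER's canonical residue order.  The reader
and writer handle the plain-text ``.hmm`` format produced by ``hmmbuild``
(header lines ``NAME``/``ACC``/``LENG``/``ALPH``, the ``HMM`` alphabet line,
the optional ``COMPO`` line, and the per-node emission/transition triplets).
Only single-model amino-acid files are supported; DNA models and pressed
binary files are not.

Stored values in the file are negative natural logs of probabilities, with
``*`` denoting probability zero; in memory everything is kept as plain
probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, TextIO

import numpy as np

#: HMMER canonical amino-acid ordering.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Transition column order in HMMER3 files (out of node k).
TRANSITION_ORDER = ("mm", "mi", "md", "im", "ii", "dm", "dd")


@dataclass
class ProfileHMM:
    """One protein-domain profile HMM (core model states only).

    Parameters
    ----------
    name : str
        Model name (``NAME`` line).
    length : int
        Number of match states, >= 1.
    match_emissions : ndarray, shape (length, 20)
        Match-state emission probabilities, rows sum to 1.
    insert_emissions : ndarray, shape (length, 20)
        Insert-state emission probabilities.
    transitions : ndarray, shape (length, 7)
        Per-node transition probabilities in :data:`TRANSITION_ORDER`.
        Row k holds the transitions out of node k+1; the ``md``/``dd``
        entries of the final row are zero (no node to delete into).
    background : ndarray, shape (20,)
        Background residue frequencies used for log-odds scoring; uniform
        1/20 unless the caller supplies something else.
    family : str or None
        Gene-family label (e.g. ``GH5``); usually assigned from a catalog.
    """

    name: str
    length: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 1.0 / 20.0)
    )
    family: str | None = None

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.length < 1:
            raise ValueError("profile must have at least one match state")
        if self.match_emissions.shape != (self.length, 20):
            raise ValueError(
                f"match emissions shape {self.match_emissions.shape} "
                f"inconsistent with length {self.length}"
            )
        if self.insert_emissions.shape != (self.length, 20):
            raise ValueError("insert emissions shape inconsistent with length")
        if self.transitions.shape != (self.length, 7):
            raise ValueError("transitions shape inconsistent with length")
        rows = self.match_emissions.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("match emission rows must sum to 1")

    # -- log-odds views used by the Viterbi scorer ---------------------------

    def match_log_odds(self) -> np.ndarray:
        """log2(match emission / background), shape (length, 20)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.match_emissions) - np.log2(self.background)

    def insert_log_odds(self) -> np.ndarray:
        """log2(insert emission / background), shape (length, 20)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.insert_emissions) - np.log2(self.background)

    def transition_log2(self) -> np.ndarray:
        """log2 transition probabilities, shape (length, 7); -inf for zero."""
        with np.errstate(divide="ignore"):
            return np.log2(self.transitions)


def _format_row(values: np.ndarray) -> str:
    out = []
    for v in values:
        if v <= 0.0:
            out.append("*")
        else:
            out.append(f"{-math.log(v):.5f}")
    return "  ".join(f"{s:>9s}" for s in out)


def _parse_row(tokens: list[str]) -> np.ndarray:
    vals = np.empty(len(tokens))
    for i, tok in enumerate(tokens):
        vals[i] = 0.0 if tok == "*" else math.exp(-float(tok))
    return vals


def write_hmm(profile: ProfileHMM, handle: TextIO) -> None:
    """Write one profile in HMMER3 ASCII format."""
    handle.write("HMMER3/f [ghminer]\n")
    handle.write(f"NAME  {profile.name}\n")
    if profile.family:
        handle.write(f"ACC   {profile.family}\n")
    handle.write(f"LENG  {profile.length}\n")
    handle.write("ALPH  amino\n")
    handle.write(
        "HMM          "
        + "  ".join(f"{a:>7s}" for a in AMINO_ACIDS)
        + "\n"
    )
    handle.write(
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n"
    )
    # node 0: begin-state insert emissions and transitions (uniform filler;
    # the local scorer does not use node 0)
    uniform = np.full(20, 1.0 / 20.0)
    node0_trans = np.array([0.99, 0.005, 0.005, 0.5, 0.5, 0.0, 0.0])
    handle.write("  COMPO  " + _format_row(profile.match_emissions.mean(axis=0)) + "\n")
    handle.write("         " + _format_row(uniform) + "\n")
    handle.write("         " + _format_row(node0_trans) + "\n")
    for k in range(profile.length):
        consensus = AMINO_ACIDS[int(np.argmax(profile.match_emissions[k]))]
        handle.write(
            f"{k + 1:>7d}  "
            + _format_row(profile.match_emissions[k])
            + f"  {k + 1:>6d} {consensus.lower()} - - -\n"
        )
        handle.write("         " + _format_row(profile.insert_emissions[k]) + "\n")
        handle.write("         " + _format_row(profile.transitions[k]) + "\n")
    handle.write("//\n")


def write_hmm_file(profiles: list[ProfileHMM] | ProfileHMM, path: str | Path) -> None:
    if isinstance(profiles, ProfileHMM):
        profiles = [profiles]
    with open(path, "w") as fh:
        for p in profiles:
            write_hmm(p, fh)


def _read_one(lines: Iterator[str], first: str) -> ProfileHMM | None:
    name = None
    family = None
    length = None
    alph = None
    line = first
    while True:
        if line.startswith("NAME"):
            name = line.split(maxsplit=1)[1].strip()
        elif line.startswith("ACC"):
            family = line.split(maxsplit=1)[1].strip()
        elif line.startswith("LENG"):
            length = int(line.split()[1])
        elif line.startswith("ALPH"):
            alph = line.split()[1].strip().lower()
        elif line.startswith("HMM "):
            break
        line = next(lines)
    if name is None or length is None:
        raise ValueError("missing NAME or LENG header line")
    if alph != "amino":
        raise ValueError(f"unsupported alphabet {alph!r}; only amino supported")
    order = line.split()[1:]
    if "".join(order) != AMINO_ACIDS:
        raise ValueError("unexpected residue ordering in HMM alphabet line")
    next(lines)  # transition header
    row = next(lines).split()
    if row[0] == "COMPO":
        next(lines)  # node-0 insert emissions
        next(lines)  # node-0 transitions
    else:
        # no COMPO: the row just read was node-0 insert emissions
        next(lines)
    match_em = np.empty((length, 20))
    insert_em = np.empty((length, 20))
    trans = np.empty((length, 7))
    for k in range(length):
        mrow = next(lines).split()
        if int(mrow[0]) != k + 1:
            raise ValueError(f"node numbering broken at node {k + 1}")
        match_em[k] = _parse_row(mrow[1:21])
        insert_em[k] = _parse_row(next(lines).split()[:20])
        trans[k] = _parse_row(next(lines).split()[:7])
    closing = next(lines).strip()
    if closing != "//":
        raise ValueError("model not terminated by //")
    return ProfileHMM(
        name=name,
        length=length,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        family=family,
    )


def read_hmm_file(path: str | Path) -> list[ProfileHMM]:
    """Read all models from a HMMER3 ASCII file."""
    profiles: list[ProfileHMM] = []
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            if line.startswith("HMMER3"):
                first = next(lines)
                profiles.append(_read_one(lines, first))
    if not profiles:
        raise ValueError(f"no profile models found in {path}")
    return profiles
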