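"""Seq-Gen-style sequence simulation under K2P + I + discrete Gamma.

Each site independently draws a rate category from the mixture weights; a
root state is drawn from the uniform stationary distribution and evolved
down the tree by sampling from the per-branch transition matrices
(pre-order node-by-node sampling, exact under the Markov model). Sites in
the zero-rate category are by construction identical across all taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import K2PModel, RateMixture, STATIONARY_FREQS, k2p_transition_matrix
from .trees import PhyloTree

__all__ = ["Alignment", "simulate_alignment", "read_alignment", "write_alignment"]

logger = logging.getLogger("phyloem")

_ALPHABET = np.frombuffer(b"ACGT", dtype="S1")
#: integer code for missing data (gap or N)
MISSING = 4

_CODE = np.full(256, MISSING, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


@dataclass
class Alignment:
    """A multiple sequence alignment of equal-length DNA sequences.

    ``codes`` is an (n_taxa, n_sites) int8 matrix with A,C,G,T -> 0..3 and
    anything else (gap, N, ambiguity) -> 4 (missing).
    """

    labels: list[str]
    codes: np.ndarray
    #: per-site true rate category from the simulator, if known
    true_categories: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.labels):
            raise ValueError("codes must be (n_taxa, n_sites) matching labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxon labels")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, i: int) -> str:
        chars = np.where(
            self.codes[i] < 4, _ALPHABET[np.clip(self.codes[i], 0, 3)], b"N"
        )
        return chars.tobytes().decode()

    @classmethod
    def from_sequences(cls, labels: list[str], seqs: list[str]) -> "Alignment":
        if len(labels) != len(seqs):
            raise ValueError("labels and sequences differ in number")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError("ragged alignment: sequences differ in length")
        n = lengths.pop() if lengths else 0
        codes = np.empty((len(seqs), n), dtype=np.int8)
        n_unknown = 0
        for i, s in enumerate(seqs):
            raw = np.frombuffer(s.encode(), dtype=np.uint8)
            codes[i] = _CODE[raw]
            n_unknown += int(
                np.sum((codes[i] == MISSING) & ~np.isin(raw, list(b"-Nn.?")))
            )
        if n_unknown:
            logger.warning(
                "%d non-ACGT characters mapped to missing (N)", n_unknown
            )
        return cls(labels=list(labels), codes=codes)


def simulate_alignment(
    tree: PhyloTree,
    model: K2PModel,
    mixture: RateMixture,
    n_sites: int,
    seed: int,
) -> Alignment:
    """Simulate an alignment along ``tree`` under K2P + I + discrete Gamma.

    Deterministic given ``seed``: one NumPy Generator drives the category
    draws, the root states, and the branch-by-branch descent in a fixed
    (pre-order) node order. The true per-site category is kept on the
    returned alignment for diagnostics.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    rng = np.random.default_rng(seed)
    ncat = mixture.n_categories
    cats = rng.choice(ncat, size=n_sites, p=mixture.weights)
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    states[tree.root] = rng.choice(4, size=n_sites, p=STATIONARY_FREQS)
    # per-branch, per-category cumulative transition rows
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        t = float(tree.lengths[v])
        cum = np.cumsum(
            k2p_transition_matrix(t * mixture.rates, model.kappa), axis=-1
        )  # (ncat, 4, 4)
        u = rng.random(n_sites)
        parent_states = states[p]
        rows = cum[cats, parent_states]  # (n_sites, 4)
        states[v] = np.int8(np.sum(u[:, None] > rows[:, :3], axis=1))
    leaf_idx = tree.leaf_indices()
    return Alignment(
        labels=[tree.labels[i] for i in leaf_idx],
        codes=states[leaf_idx],
        true_categories=cats,
    )


# -- file I/O -------------------------------------------------------------


def write_alignment(
    aln: Alignment, path: str | Path, fmt: str = "fasta"
) -> None:
    """Write FASTA (wrapped at 80 columns) or sequential relaxed PHYLIP."""
    path = Path(path)
    if fmt == "fasta":
        records = [
            SeqRecord(Seq(aln.sequence(i)), id=aln.labels[i], description="")
            for i in range(aln.n_taxa)
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    elif fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f" {aln.n_taxa} {aln.n_sites}\n")
            width = max(len(l) for l in aln.labels) + 2
            for i in range(aln.n_taxa):
                fh.write(f"{aln.labels[i]:<{width}}{aln.sequence(i)}\n")
    else:
        raise ValueError(f"unknown alignment format: {fmt!r}")


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read a FASTA or relaxed sequential PHYLIP alignment.

    The format is sniffed from the first character when not given.
    Non-ACGT characters become missing (N) with a logged warning; ragged
    sequences raise a format error.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.read(1)
        fmt = "fasta" if first == ">" else "phylip"
    if fmt == "fasta":
        labels, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            seqs.append(str(rec.seq))
        if not labels:
            raise ValueError(f"no sequences found in {path}")
        return Alignment.from_sequences(labels, seqs)
    if fmt == "phylip":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) < 2:
                raise ValueError(f"bad PHYLIP header in {path}")
            ntax, nsites = int(header[0]), int(header[1])
            labels, seqs = [], []
            for line in fh:
                if not line.strip():
                    continue
                parts = line.split(None, 1)
                if len(parts) == 1:  # interleaved continuation unsupported
                    raise ValueError(
                        "only sequential PHYLIP (name + sequence per line) "
                        "is supported"
                    )
                labels.append(parts[0])
                seqs.append(parts[1].replace(" ", "").strip())
        if len(labels) != ntax:
            raise ValueError(
                f"PHYLIP header promises {ntax} taxa, found {len(labels)}"
            )
        if any(len(s) != nsites for s in seqs):
            raise ValueError("PHYLIP sequences do not match header length")
        return Alignment.from_sequences(labels, seqs)
    raise ValueError(f"unknown alignment format: {fmt!r}")
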