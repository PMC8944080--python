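"""Enzyme-mining pipeline for tryptophanase candidate selection.

Mirrors a bioprospecting workflow over bacterial protein databases: reduce the
raw hit list to one representative per species, compute an all-vs-all percent
identity matrix by global alignment, cluster the sequences hierarchically on
the distance 1 - identity, cut the tree into k families, filter candidates on
length / theoretical mass / host annotations, and pick one diverse
representative per cluster.

The global aligner is a Needleman–Wunsch dynamic program with linear gap
penalties and a fixed traceback preference (diagonal, then up, then left) so
results are bit-reproducible.  Percent identity uses the full alignment length
(gap columns included) as the denominator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data.IUPACData import protein_weights
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_VALID_CHARS = set(AA_ALPHABET) | {"X"}

#: average residue masses (free amino acid minus one water), Da
_WATER = 18.0153
_RESIDUE_MASS = {aa: protein_weights[aa] - _WATER for aa in AA_ALPHABET}
_RESIDUE_MASS["X"] = sum(_RESIDUE_MASS[a] for a in AA_ALPHABET) / 20.0


# ---------------------------------------------------------------------------
# records and FASTA I/O
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """One annotated protein sequence.

    Annotations are free-form key/value pairs; the pipeline understands
    ``pfam_pf01212_present`` and ``pathogenic_host`` booleans and a numeric
    ``family`` truth label when present.
    """

    id: str
    species: str
    sequence: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValueError(f"record {self.id!r}: illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def theoretical_mass_kda(self) -> float:
        """Peptide mass from average residue masses plus one water, in kDa."""
        return (sum(_RESIDUE_MASS[c] for c in self.sequence) + _WATER) / 1000.0


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    return str(v).replace(" ", "_")


def _parse_value(s: str):
    if s == "true":
        return True
    if s == "false":
        return False
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def read_fasta(path) -> list[SequenceRecord]:
    """Read records whose FASTA headers follow ``>id key=value ...``.

    The ``species=`` token is mandatory (spaces encoded as underscores);
    remaining tokens become annotations with booleans and numbers parsed.
    """
    records: list[SequenceRecord] = []
    errors: list[str] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        tokens = rec.description.split()[1:]  # first token repeats the id
        kv = {}
        for tok in tokens:
            if "=" in tok:
                k, _, v = tok.partition("=")
                kv[k] = _parse_value(v)
        species = kv.pop("species", None)
        if species is None:
            errors.append(f"record #{i} ({rec.id}): missing species= token")
            continue
        if len(rec.seq) == 0:
            errors.append(f"record #{i} ({rec.id}): empty sequence")
            continue
        records.append(SequenceRecord(
            id=rec.id, species=str(species).replace("_", " "),
            sequence=str(rec.seq).upper(), annotations=kv))
    if errors:
        raise ValueError("malformed FASTA records:\n" + "\n".join(errors))
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = []
    for r in records:
        desc = "species=" + _fmt_value(r.species)
        for k, v in r.annotations.items():
            desc += f" {k}={_fmt_value(v)}"
        bio.append(_BioSeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# deduplication, filtering, summaries
# ---------------------------------------------------------------------------

def dedupe_by_species(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Keep one representative per species: the longest, ties by smaller id."""
    missing = [r.id for r in records if not r.species]
    if missing:
        raise ValueError(f"records without species annotation: {missing}")
    best: dict[str, SequenceRecord] = {}
    for r in records:
        cur = best.get(r.species)
        if cur is None or (r.length, _neg_id(r.id)) > (cur.length, _neg_id(cur.id)):
            best[r.species] = r
    # preserve input order of the surviving records
    keep = {id(v) for v in best.values()}
    return [r for r in records if id(r) in keep]


class _neg_id(str):
    """Reverses string comparison so max() picks the lexicographically smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


@dataclass(frozen=True)
class FilterRules:
    """Candidate admissibility rules, applied in declaration order."""

    min_length: Optional[int] = None
    max_length: Optional[int] = None
    mass_window_kda: Optional[tuple[float, float]] = None
    require_flags: tuple[str, ...] = ()
    exclude_flags: tuple[str, ...] = ()


def filter_candidates(records: Sequence[SequenceRecord],
                      rules: Optional[FilterRules] = None
                      ) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Split records into (kept, discarded-with-reason) under the rules.

    Each discarded record carries the first rule it violated: length bounds,
    then the theoretical-mass window, then required / excluded annotation flags.
    """
    if rules is None:
        return list(records), []
    kept, discarded = [], []
    for r in records:
        reason = None
        if rules.min_length is not None and r.length < rules.min_length:
            reason = f"length {r.length} < min_length {rules.min_length}"
        elif rules.max_length is not None and r.length > rules.max_length:
            reason = f"length {r.length} > max_length {rules.max_length}"
        elif rules.mass_window_kda is not None:
            lo, hi = rules.mass_window_kda
            m = r.theoretical_mass_kda()
            if not (lo <= m <= hi):
                reason = f"theoretical mass {m:.1f} kDa outside [{lo}, {hi}]"
        if reason is None:
            for flag in rules.require_flags:
                if not r.annotations.get(flag, False):
                    reason = f"missing required flag {flag}"
                    break
        if reason is None:
            for flag in rules.exclude_flags:
                if r.annotations.get(flag, False):
                    reason = f"excluded flag {flag}"
                    break
        if reason is None:
            kept.append(r)
        else:
            discarded.append((r, reason))
    return kept, discarded


@dataclass(frozen=True)
class LengthSummary:
    n: int
    mean: float
    sd: float
    min: int
    max: int


def cluster_summary(records: Sequence[SequenceRecord]) -> LengthSummary:
    """Length statistics (sample SD, n-1 denominator; 0 for a single record)."""
    if not records:
        raise ValueError("need at least one record")
    lengths = [r.length for r in records]
    n = len(lengths)
    mean = sum(lengths) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in lengths) / (n - 1)) if n > 1 else 0.0
    return LengthSummary(n=n, mean=mean, sd=sd, min=min(lengths), max=max(lengths))


# ---------------------------------------------------------------------------
# global alignment and identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -1.0  # linear gap penalty per residue


@dataclass(frozen=True)
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float


def global_align(a: str, b: str, scoring: Scoring = Scoring()) -> Alignment:
    """Optimal Needleman–Wunsch global alignment with linear gaps.

    Traceback ties are broken deterministically: diagonal first, then up
    (gap in ``b``), then left (gap in ``a``).
    """
    for s, name in ((a, "a"), (b, "b")):
        if not s:
            raise ValueError(f"sequence {name} is empty")
        bad = set(s) - _VALID_CHARS
        if bad:
            raise ValueError(f"sequence {name}: illegal characters {sorted(bad)}")
    n, m = len(a), len(b)
    gap = scoring.gap
    H = np.empty((n + 1, m + 1))
    H[0, :] = np.arange(m + 1) * gap
    H[:, 0] = np.arange(n + 1) * gap
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(a_arr[:, None] == b_arr[None, :], scoring.match, scoring.mismatch)
    for i in range(1, n + 1):
        prev, cur = H[i - 1], H[i]
        diag = prev[:-1] + sub[i - 1]
        up = prev[1:] + gap
        best = np.maximum(diag, up)
        # the left-dependency forces a scan within the row
        run = cur[0]
        row = H[i]
        for j in range(1, m + 1):
            run = max(best[j - 1], run + gap)
            row[j] = run
    # deterministic traceback: diagonal > up > left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = H[i, j]
        if i > 0 and j > 0 and here == H[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and here == H[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     float(H[n, m]))


def percent_identity(alignment: Alignment) -> float:
    """Identical columns / total alignment columns (gaps count in the denominator)."""
    a, b = alignment.aligned_a, alignment.aligned_b
    if len(a) != len(b):
        raise ValueError("aligned strings differ in length")
    if not a:
        raise ValueError("empty alignment")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


@dataclass
class IdentityMatrix:
    ids: list[str]
    identity: np.ndarray  # square, symmetric, unit diagonal

    def distance(self) -> np.ndarray:
        return 1.0 - self.identity

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.identity, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "IdentityMatrix":
        import pandas as pd
        df = pd.read_csv(path, index_col=0)
        return cls(ids=list(df.index), identity=df.to_numpy(dtype=float))


def identity_matrix(records: Sequence[SequenceRecord],
                    scoring: Scoring = Scoring()) -> IdentityMatrix:
    """All-vs-all percent identity by global alignment, each pair aligned once."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    n = len(records)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                aln = global_align(records[i].sequence, records[j].sequence, scoring)
            except ValueError as exc:
                raise ValueError(
                    f"alignment failed for pair ({records[i].id}, "
                    f"{records[j].id}): {exc}") from exc
            mat[i, j] = mat[j, i] = percent_identity(aln)
    return IdentityMatrix(ids=[r.id for r in records], identity=mat)


# ---------------------------------------------------------------------------
# hierarchical clustering on 1 - identity
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Agglomeration history: n-1 merges of (cluster_i, cluster_j, height, size).

    Cluster indices follow the scipy linkage convention: leaves are 0..n-1 and
    the cluster created by merge t gets index n+t.
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    linkage: str = "complete"

    def to_linkage_matrix(self) -> np.ndarray:
        return np.array([[i, j, h, s] for i, j, h, s in self.merges], dtype=float)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "n_leaves": self.n_leaves, "linkage": self.linkage,
            "merges": self.merges}, indent=1))


_LINKAGES = {
    "complete": lambda d1, d2, n1, n2: max(d1, d2),
    "single": lambda d1, d2, n1, n2: min(d1, d2),
    "average": lambda d1, d2, n1, n2: (n1 * d1 + n2 * d2) / (n1 + n2),
}


def hierarchical_cluster(distance: np.ndarray, linkage: str = "complete") -> ClusterTree:
    """Agglomerative clustering of a square distance matrix.

    At each step the pair of active clusters with the smallest inter-cluster
    distance merges; ties go to the lexicographically smallest index pair.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance must be a square matrix")
    if np.any(np.isnan(D)):
        raise ValueError("distance matrix contains NaN")
    n = D.shape[0]
    update = _LINKAGES[linkage]

    # inter-cluster distances keyed by frozenset of active cluster indices
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    active = sorted(sizes)
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (ci, cj), h = best
        ni, nj = sizes.pop(ci), sizes.pop(cj)
        new = next_id
        next_id += 1
        active = [c for c in active if c not in (ci, cj)]
        for other in active:
            d1 = dist.pop(tuple(sorted((ci, other))))
            d2 = dist.pop(tuple(sorted((cj, other))))
            dist[(other, new)] = update(d1, d2, ni, nj)
        del dist[(ci, cj)]
        sizes[new] = ni + nj
        active.append(new)
        merges.append((ci, cj, h, ni + nj))
    return ClusterTree(n_leaves=n, merges=merges, linkage=linkage)


@dataclass
class ClusterAssignment:
    """id -> contiguous cluster label in 1..k, labelled by order of first member."""

    labels: dict[str, int]
    k: int

    def as_array(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[i] for i in ids])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tcluster\n")
            for i, c in self.labels.items():
                fh.write(f"{i}\t{c}\n")


def cut_tree(tree: ClusterTree, ids: Sequence[str], *,
             k: Optional[int] = None, height: Optional[float] = None
             ) -> ClusterAssignment:
    """Cut an agglomeration into flat clusters by count ``k`` or by ``height``.

    Cutting by k replays the first n-k merges; cutting by height replays all
    merges at or below the threshold.  Labels are contiguous 1..k in order of
    each cluster's first member in the input ordering.
    """
    n = tree.n_leaves
    if len(ids) != n:
        raise ValueError("ids length must equal number of leaves")
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k={k} out of range 1..{n}")
        n_merges = n - k
    else:
        if height < 0:
            raise ValueError("height must be >= 0")
        n_merges = sum(1 for _, _, h, _ in tree.merges if h <= height)

    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n_merges):
        i, j, _, _ = tree.merges[t]
        new = n + t
        parent[find(i)] = new
        parent[find(j)] = new

    label_of_root: dict[int, int] = {}
    labels: dict[str, int] = {}
    for idx, rid in enumerate(ids):
        root = find(idx)
        if root not in label_of_root:
            label_of_root[root] = len(label_of_root) + 1
        labels[rid] = label_of_root[root]
    return ClusterAssignment(labels=labels, k=len(label_of_root))


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------

def select_representatives(assignment: ClusterAssignment,
                           records: Sequence[SequenceRecord],
                           matrix: IdentityMatrix,
                           rules: Optional[FilterRules] = None
                           ) -> tuple[list[SequenceRecord], list[int]]:
    """Greedy diverse candidate per cluster.

    Clusters are visited in label order; within each, among records passing
    the filter rules, the one maximizing mean distance (1 - identity) to the
    already-selected candidates wins (ties by id; the very first pick, with
    nothing selected yet, also falls back to the smallest id).  Returns the
    candidates plus the labels of clusters with no admissible member.
    """
    by_id = {r.id: r for r in records}
    missing = [i for i in assignment.labels if i not in by_id]
    if missing:
        raise ValueError(f"assignment covers unknown ids: {missing}")
    index_of = {rid: i for i, rid in enumerate(matrix.ids)}
    dist = matrix.distance()

    admissible, _ = filter_candidates(records, rules)
    admissible_ids = {r.id for r in admissible}

    clusters: dict[int, list[str]] = {}
    for rid, lab in assignment.labels.items():
        clusters.setdefault(lab, []).append(rid)

    selected: list[SequenceRecord] = []
    empty: list[int] = []
    for lab in sorted(clusters):
        pool = sorted(rid for rid in clusters[lab] if rid in admissible_ids)
        if not pool:
            empty.append(lab)
            continue
        if not selected:
            choice = pool[0]
        else:
            sel_idx = [index_of[r.id] for r in selected]
            choice = max(pool, key=lambda rid: (
                float(np.mean(dist[index_of[rid], sel_idx])), _neg_id(rid)))
        selected.append(by_id[choice])
    return selected, empty
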