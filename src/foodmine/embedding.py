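"""Substructure-sentence chemical embeddings with health-association overlay.

Each molecule is rendered as an ordered "sentence" of Morgan (circular)
substructure identifiers — for every atom, in canonical atom order, the
environment identifier at each radius 0..r. Token vectors are learned with
a skip-gram / negative-sampling objective over the sentence corpus; a
molecule's embedding is the sum of its token vectors (unseen tokens share a
single UNK vector). Embeddings are reduced to 2-D (t-SNE by default, PCA as
an exactly deterministic alternative) and annotated with per-compound
health-association counts and database membership, mirroring how curated
chemical-disease association totals are overlaid on a chemical map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "SubstructureSentence",
    "ChemEmbedding",
    "TokenTable",
    "sentence",
    "train_embedding",
    "embed_compound",
    "reduce_2d",
    "overlay_health",
]


class StructureError(ValueError):
    """Raised for SMILES strings RDKit cannot parse; carries the string."""


@dataclass(frozen=True)
class SubstructureSentence:
    """Ordered Morgan-identifier tokens for one molecule.

    Token count is exactly atom_count * (radius + 1): an atom lacking an
    environment at some radius (e.g. a lone heavy atom at radius 1) repeats
    its largest available identifier so positional structure is preserved.
    """

    cid: int
    tokens: tuple[str, ...]


def sentence(smiles: str, radius: int = 1, cid: int = 0) -> SubstructureSentence:
    """Build the substructure sentence of a molecule, deterministically.

    The molecule is re-canonicalized first, so any SMILES spelling of the
    same structure yields the identical sentence.
    """
    if radius not in (1, 2):
        raise ValueError("radius must be 1 or 2")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))  # canonical atom order
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(mol, additionalOutput=ao)
    per_atom: dict[int, dict[int, int]] = {}
    for identifier, hits in ao.GetBitInfoMap().items():
        for atom_idx, rad in hits:
            per_atom.setdefault(atom_idx, {})[rad] = identifier
    tokens: list[str] = []
    for atom_idx in range(mol.GetNumAtoms()):
        envs = per_atom.get(atom_idx, {})
        last = None
        for r in range(radius + 1):
            if r in envs:
                last = envs[r]
            tokens.append(str(last))
    return SubstructureSentence(cid=cid, tokens=tuple(tokens))


@dataclass
class ChemEmbedding:
    """A compound's dense structural vector plus overlay annotations."""

    cid: int
    vector: np.ndarray
    coords2d: tuple[float, float] | None = None
    health_count: int | None = None
    in_databases: frozenset[str] = frozenset()


@dataclass
class TokenTable:
    """Learned token vectors plus a shared unknown-token vector."""

    vectors: dict[str, np.ndarray]
    unk: np.ndarray
    dim: int

    def get(self, token: str) -> np.ndarray:
        return self.vectors.get(token, self.unk)


def train_embedding(sentences: Sequence[SubstructureSentence], d: int = 32,
                    seed: int = 0, window: int = 5, epochs: int = 40,
                    negatives: int = 5, lr: float = 0.025) -> TokenTable:
    """Learn token vectors by skip-gram with negative sampling.

    A compact numpy SGD trainer suited to desk-scale substructure corpora:
    for each (center, context) pair within ``window``, the center vector is
    pushed toward the context's output vector and away from ``negatives``
    tokens drawn from the unigram^0.75 distribution. Single-threaded and
    fully reproducible given ``seed``.
    """
    if d <= 0:
        raise ValueError("embedding dimension must be positive")
    if not sentences:
        raise ValueError("sentence corpus is empty")
    vocab: dict[str, int] = {}
    counts: list[int] = []
    corpus: list[np.ndarray] = []
    for sent in sentences:
        ids = []
        for tok in sent.tokens:
            if tok not in vocab:
                vocab[tok] = len(vocab)
                counts.append(0)
            counts[vocab[tok]] += 1
            ids.append(vocab[tok])
        corpus.append(np.array(ids, dtype=np.int64))
    V = len(vocab)
    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))
    noise = np.array(counts, dtype=float) ** 0.75
    noise /= noise.sum()

    for epoch in range(epochs):
        alpha = lr * max(0.1, 1.0 - epoch / epochs)
        order = rng.permutation(len(corpus))
        for si in order:
            ids = corpus[si]
            for pos, center in enumerate(ids):
                lo = max(0, pos - window)
                hi = min(len(ids), pos + window + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    ctx = ids[ctx_pos]
                    targets = np.concatenate(
                        ([ctx], rng.choice(V, size=negatives, p=noise)))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    v = W_in[center]
                    u = W_out[targets]
                    scores = 1.0 / (1.0 + np.exp(-u @ v))
                    g = (scores - labels) * alpha
                    W_in[center] -= g @ u
                    W_out[targets] -= np.outer(g, v)
    vectors = {tok: W_in[idx].copy() for tok, idx in vocab.items()}
    unk = np.zeros(d) if V == 0 else np.mean(W_in, axis=0)
    return TokenTable(vectors=vectors, unk=unk, dim=d)


def embed_compound(sent: SubstructureSentence, table: TokenTable) -> ChemEmbedding:
    """Molecule vector = sum of its token vectors (UNK for unseen tokens)."""
    vec = np.zeros(table.dim)
    for tok in sent.tokens:
        vec = vec + table.get(tok)
    return ChemEmbedding(cid=sent.cid, vector=vec)


def reduce_2d(embeddings: Sequence[ChemEmbedding], perplexity: float = 5.0,
              seed: int = 0, method: str = "tsne") -> list[ChemEmbedding]:
    """Fill 2-D coordinates by t-SNE (default) or PCA.

    t-SNE requires at least 3 * perplexity points for stable geometry; PCA
    is offered as an exactly deterministic alternative for pipelines that
    must be byte-reproducible.
    """
    X = np.vstack([e.vector for e in embeddings]) if embeddings else np.empty((0, 0))
    if method == "tsne":
        if len(embeddings) < 3 * perplexity:
            raise ValueError(
                f"{len(embeddings)} points is too few for perplexity "
                f"{perplexity}; need at least {int(3 * perplexity)}"
            )
        from sklearn.manifold import TSNE

        coords = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                      init="pca").fit_transform(X)
    elif method == "pca":
        if len(embeddings) < 2:
            raise ValueError("PCA reduction needs at least 2 points")
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    else:
        raise ValueError(f"unknown reduction method {method!r}")
    out = []
    for e, (x, y) in zip(embeddings, coords):
        out.append(ChemEmbedding(cid=e.cid, vector=e.vector,
                                 coords2d=(float(x), float(y)),
                                 health_count=e.health_count,
                                 in_databases=e.in_databases))
    return out


def overlay_health(embeddings: Sequence[ChemEmbedding],
                   associations: Mapping[int, int],
                   membership: Mapping[int, Iterable[str]]):
    """Attach health-association counts and database membership.

    Returns the annotated embeddings and, per database, the number and
    fraction of member chemicals with at least one association. Compounds
    missing from the association map keep ``health_count=None`` and are
    reported as unmatched.
    """
    for count in associations.values():
        if count < 0:
            raise ValueError("association counts must be nonnegative")
    annotated = []
    summary: dict[str, dict[str, float]] = {}
    members: dict[str, list[ChemEmbedding]] = {}
    for e in embeddings:
        dbs = frozenset(membership.get(e.cid, ()))
        count = associations.get(e.cid)
        ann = ChemEmbedding(cid=e.cid, vector=e.vector, coords2d=e.coords2d,
                            health_count=count, in_databases=dbs)
        annotated.append(ann)
        for db in dbs:
            members.setdefault(db, []).append(ann)
    for db in sorted(members):
        mem = members[db]
        n_assoc = sum(1 for e in mem
                      if e.health_count is not None and e.health_count > 0)
        summary[db] = {
            "n_members": len(mem),
            "n_with_associations": n_assoc,
            "fraction_with_associations": n_assoc / len(mem) if mem else 0.0,
            "total_associations": float(sum(e.health_count or 0 for e in mem)),
        }
    n_unmatched = sum(1 for e in annotated if e.health_count is None)
    return annotated, {"per_database": summary, "n_unmatched": n_unmatched}
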