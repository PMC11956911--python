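"""Model-agnostic contract for obtaining token embeddings and attention.

An encoder protein language model (PLM) maps a length-``n`` amino-acid
sequence to an ``n_tok x d`` token-embedding matrix and a stack of ``L``
post-softmax attention matrices (``n_tok x n_tok``, one per layer after
reducing attention heads), where ``n_tok`` counts any special tokens
([CLS], end-of-sequence, padding) the tokenizer adds.  This module defines
that contract (:class:`EncoderOutput`), the residue-restricted view the
pooling pipeline consumes (:class:`ResidueView`), and two backends: a
deterministic synthetic one for tests, and a lazy HuggingFace adapter for
real ESM2/protBERT-style models.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Protocol, Sequence

import numpy as np

__all__ = [
    "EncoderOutput",
    "ResidueView",
    "EncoderBackend",
    "SyntheticBackend",
    "HuggingFaceBackend",
    "encode",
    "strip_special_tokens",
    "read_fasta",
    "VALID_RESIDUES",
]

# 20 standard amino acids plus the ambiguity/rare codes X, B, Z, U, O.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZUO")

_ROLES = ("residue", "cls", "eos", "pad")


@dataclass
class EncoderOutput:
    """Raw forward-pass output of an encoder PLM, special tokens included.

    ``raw_attention`` has shape ``(L, n_tok, n_tok)`` with row-stochastic
    layers (post-softmax); ``token_roles`` tags each of the ``n_tok``
    positions as residue/cls/eos/pad.
    """

    raw_embeddings: np.ndarray
    raw_attention: np.ndarray
    token_roles: tuple[str, ...]
    model_id: str
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.raw_embeddings = np.asarray(self.raw_embeddings, dtype=float)
        self.raw_attention = np.asarray(self.raw_attention, dtype=float)
        n_tok = self.raw_embeddings.shape[0]
        if self.raw_attention.ndim != 3 or self.raw_attention.shape[1:] != (n_tok, n_tok):
            raise ValueError(
                f"raw_attention must be (L, {n_tok}, {n_tok}), got {self.raw_attention.shape}"
            )
        if len(self.token_roles) != n_tok:
            raise ValueError("token_roles length must match raw_embeddings rows")
        bad = [r for r in self.token_roles if r not in _ROLES]
        if bad:
            raise ValueError(f"unknown token roles: {sorted(set(bad))}")
        rowsums = self.raw_attention.sum(axis=2)
        if not np.allclose(rowsums, 1.0, atol=1e-4):
            raise ValueError("attention rows must sum to 1 within 1e-4 (post-softmax)")
        pads = [i for i, r in enumerate(self.token_roles) if r == "pad"]
        if pads and pads != list(range(n_tok - len(pads), n_tok)):
            raise ValueError("pad positions must be contiguous at the end")

    @property
    def n_residues(self) -> int:
        return sum(r == "residue" for r in self.token_roles)


@dataclass
class ResidueView:
    """Residue-restricted encoder output: the input to the pooling pipeline.

    ``attention`` rows need not sum to 1 any more — removing special-token
    columns removes mass; downstream PageRank renormalizes rows itself.
    ``cls_embedding`` is retained separately when the model has a [CLS]
    token (required by the CLS-pooling baseline), else ``None``.
    """

    embeddings: np.ndarray
    attention: np.ndarray
    sequence: str
    cls_embedding: np.ndarray | None = None
    model_id: str = ""
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.attention = np.asarray(self.attention, dtype=float)
        n = len(self.sequence)
        if self.embeddings.shape[0] != n:
            raise ValueError("embedding rows must equal sequence length")
        if self.attention.ndim != 3 or self.attention.shape[1:] != (n, n):
            raise ValueError("attention must be (L, n, n) over residues")
        if (self.attention < 0).any():
            raise ValueError("attention entries must be non-negative")

    @property
    def n(self) -> int:
        return len(self.sequence)


class EncoderBackend(Protocol):
    """Handle for a loaded encoder model."""

    model_id: str
    max_length: int

    def encode_tokens(self, sequence: str) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
        """Return (embeddings, attention, token_roles).

        ``attention`` may be 3-D ``(L, n_tok, n_tok)`` (pre-reduced heads) or
        4-D ``(L, H, n_tok, n_tok)``; :func:`encode` reduces heads.
        """
        ...


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pos, aa in enumerate(sequence, start=1):
        if aa.upper() not in VALID_RESIDUES:
            raise ValueError(
                f"invalid residue {aa!r} at position {pos}: alphabet is the 20 "
                "standard amino acids plus X/B/Z/U/O"
            )


def encode(
    sequence: str,
    backend: EncoderBackend,
    *,
    head_reduction: str = "max",
    sequence_id: str = "",
) -> EncoderOutput:
    """Run a forward pass and return the per-layer attention stack.

    If the backend exposes per-head attention, heads are reduced within each
    layer here — element-wise ``max`` by default, so the subsequent
    cross-layer max equals a single max over all layer-head matrices;
    ``mean`` is available for ablation.

    Raises an explicit error for sequences longer than the backend's context
    window (no silent truncation) and for characters outside the amino-acid
    alphabet.
    """
    _validate_sequence(sequence)
    if len(sequence) > backend.max_length:
        raise ValueError(
            f"sequence length {len(sequence)} exceeds the backend's context "
            f"window of {backend.max_length} tokens ({backend.model_id})"
        )
    if head_reduction not in ("max", "mean"):
        raise ValueError("head_reduction must be 'max' or 'mean'")
    embeddings, attention, roles = backend.encode_tokens(sequence)
    attention = np.asarray(attention, dtype=float)
    if attention.ndim == 4:
        reduce = np.max if head_reduction == "max" else np.mean
        attention = reduce(attention, axis=1)
        # head-max rows can exceed 1; rescale to keep layers row-stochastic
        attention = attention / attention.sum(axis=2, keepdims=True)
    out = EncoderOutput(
        raw_embeddings=embeddings,
        raw_attention=attention,
        token_roles=tuple(roles),
        model_id=backend.model_id,
        sequence_id=sequence_id,
    )
    if out.n_residues != len(sequence):
        raise ValueError(
            f"backend returned {out.n_residues} residue tokens for a length-"
            f"{len(sequence)} sequence"
        )
    return out


def strip_special_tokens(out: EncoderOutput, sequence: str | None = None) -> ResidueView:
    """Restrict embeddings and attention to residue rows/columns.

    Order is preserved; the [CLS] embedding, when present, is kept aside for
    the CLS-pooling baseline.  Idempotent on its residue content.
    """
    idx = np.array([i for i, r in enumerate(out.token_roles) if r == "residue"], dtype=int)
    if idx.size == 0:
        raise ValueError("encoder output contains no residue tokens")
    cls_positions = [i for i, r in enumerate(out.token_roles) if r == "cls"]
    cls_embedding = out.raw_embeddings[cls_positions[0]].copy() if cls_positions else None
    if sequence is None:
        sequence = "X" * idx.size
    return ResidueView(
        embeddings=out.raw_embeddings[idx],
        attention=out.raw_attention[:, idx[:, None], idx[None, :]],
        sequence=sequence,
        cls_embedding=cls_embedding,
        model_id=out.model_id,
        sequence_id=out.sequence_id,
    )


class SyntheticBackend:
    """Deterministic drop-in encoder for tests: no model download.

    Produces ESM2-style token bookkeeping ([CLS] + residues + EOS) around a
    residue-level attention stack drawn from the synthetic generators.  The
    residue block is embedded untouched (residue rows place zero attention
    on special tokens), so ``encode`` -> ``strip_special_tokens`` round-trips
    the generated residue-level attention exactly.  Output is a pure function
    of (sequence, backend seed): the per-sequence seed is derived via CRC32.
    """

    def __init__(
        self,
        *,
        L: int = 4,
        d: int = 16,
        seed: int = 0,
        max_length: int = 1022,
        hub_positions: tuple[int, ...] | None = None,
        dominance: float = 10.0,
        n_heads: int = 1,
        with_cls: bool = True,
        model_id: str = "synthetic",
    ) -> None:
        self.L = L
        self.d = d
        self.seed = seed
        self.max_length = max_length
        self.hub_positions = hub_positions
        self.dominance = dominance
        self.n_heads = n_heads
        self.with_cls = with_cls
        self.model_id = model_id

    def _sequence_seed(self, sequence: str) -> int:
        return (zlib.crc32(sequence.encode()) ^ (self.seed & 0x7FFFFFFF)) & 0x7FFFFFFF

    def residue_attention(self, sequence: str) -> np.ndarray:
        """The planted residue-level stack for this sequence (test oracle)."""
        from .synthetic import FixtureSpec, planted_hub_attention, random_attention_stack

        spec = FixtureSpec(
            n=len(sequence),
            L=self.L,
            d=self.d,
            seed=self._sequence_seed(sequence),
            hub_positions=self.hub_positions or (0,),
            dominance=self.dominance,
        )
        if self.hub_positions is not None:
            return planted_hub_attention(spec)
        return random_attention_stack(spec)

    def encode_tokens(self, sequence: str):
        n = len(sequence)
        rng = np.random.default_rng(self._sequence_seed(sequence))
        roles = (("cls",) if self.with_cls else ()) + ("residue",) * n + ("eos",)
        n_tok = len(roles)
        offset = 1 if self.with_cls else 0

        embeddings = rng.standard_normal(size=(n_tok, self.d))
        res_block = self.residue_attention(sequence)

        if self.n_heads > 1:
            attention = np.zeros((self.L, self.n_heads, n_tok, n_tok))
            raw = rng.standard_exponential(size=(self.L, self.n_heads, n, n))
            attention[:, :, offset : offset + n, offset : offset + n] = raw / raw.sum(
                axis=3, keepdims=True
            )
            special = [i for i in range(n_tok) if roles[i] != "residue"]
            srows = rng.standard_exponential(size=(self.L, self.n_heads, len(special), n_tok))
            attention[:, :, special, :] = srows / srows.sum(axis=3, keepdims=True)
        else:
            attention = np.zeros((self.L, n_tok, n_tok))
            attention[:, offset : offset + n, offset : offset + n] = res_block
            special = [i for i in range(n_tok) if roles[i] != "residue"]
            srows = rng.standard_exponential(size=(self.L, len(special), n_tok))
            attention[:, special, :] = srows / srows.sum(axis=2, keepdims=True)
        return embeddings, attention, roles


class HuggingFaceBackend:
    """Adapter for real encoder PLMs through HuggingFace ``transformers``.

    Works with ESM2-style checkpoints (``facebook/esm2_t33_650M_UR50D``) and
    protBERT (``Rostlab/prot_bert``, which expects space-separated residues).
    Requires the optional ``torch`` and ``transformers`` dependencies; heads
    are returned unreduced (4-D) and reduced by :func:`encode`.
    """

    def __init__(self, model_id: str, *, device: str = "cpu", max_length: int | None = None):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "HuggingFaceBackend requires the optional 'plm' extra "
                "(pip install attnrank[plm])"
            ) from exc
        self.model_id = model_id
        self.device = device
        self._tokenizer = AutoTokenizer.from_pretrained(model_id)
        self._model = AutoModel.from_pretrained(model_id, output_attentions=True).to(device)
        self._model.eval()
        limit = getattr(self._model.config, "max_position_embeddings", 1024)
        self.max_length = max_length if max_length is not None else limit - 2

    def encode_tokens(self, sequence: str):  # pragma: no cover - needs torch
        import torch

        text = " ".join(sequence) if "bert" in self.model_id.lower() else sequence
        inputs = self._tokenizer(text, return_tensors="pt").to(self.device)
        with torch.no_grad():
            out = self._model(**inputs)
        embeddings = out.last_hidden_state[0].cpu().numpy()
        # (L, H, n_tok, n_tok)
        attention = torch.stack(out.attentions, dim=0)[:, 0].cpu().numpy()
        ids = inputs["input_ids"][0].tolist()
        special = set(self._tokenizer.all_special_ids)
        cls_id = self._tokenizer.cls_token_id
        eos_ids = {self._tokenizer.eos_token_id, self._tokenizer.sep_token_id}
        roles = []
        for tid in ids:
            if tid == cls_id:
                roles.append("cls")
            elif tid in eos_ids:
                roles.append("eos")
            elif tid in special:
                roles.append("pad")
            else:
                roles.append("residue")
        return embeddings, attention, tuple(roles)


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (record id, upper-cased sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    path = Path(path)
    found = False
    for record in SeqIO.parse(str(path), "fasta"):
        found = True
        yield record.id, str(record.seq).upper()
    if not found:
        raise ValueError(f"no FASTA records found in {path}")
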