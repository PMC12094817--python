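"""Readers and writers for the package's plain-text artifact formats.

Every artifact file begins with comment headers recording the package
version, the seed and a hash of the generating configuration, so reruns
with identical configs are byte-identical and traceable.

Formats: token tables (TSV, mask rendered "-"), FASTA for sequence
tracks (via Biopython, wrapped at 60 columns), trajectory records as
line-delimited JSON, world parameters as YAML, loss traces and metric
reports as CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .flow_core import StepRecord, Trajectory
from .metrics import MetricReport
from .synthetic_data import ToyWorldParams
from .types import (
    SEQUENCE,
    STRUCTURE,
    ConditionMask,
    ProteinTokens,
    TokenTrack,
    Vocabulary,
)

MASK_CHAR = "-"


def config_hash(config: Mapping[str, object]) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def header_lines(seed: int, config: Optional[Mapping[str, object]] = None) -> list[str]:
    chash = config_hash(config or {})
    return [
        f"# pairflow {__version__}",
        f"# seed={seed} config_hash={chash}",
    ]


def _token_str(token: int, vocab: Vocabulary) -> str:
    return MASK_CHAR if token == vocab.mask_index else vocab.symbols[token]


def write_token_table(
    path: str | Path,
    proteins: Sequence[ProteinTokens],
    seq_vocab: Vocabulary,
    struct_vocab: Vocabulary,
    seed: int = 0,
    config: Optional[Mapping[str, object]] = None,
    ids: Optional[Sequence[str]] = None,
) -> None:
    """Tab-separated token table: protein id, 0-based position, sequence
    token, structure token; masks rendered as '-'."""
    if ids is None:
        ids = [f"p{i:05d}" for i in range(len(proteins))]
    lines = header_lines(seed, config)
    lines.append("protein\tposition\tseq_token\tstruct_token")
    for pid, prot in zip(ids, proteins):
        for pos in range(len(prot)):
            lines.append(
                f"{pid}\t{pos}\t"
                f"{_token_str(int(prot.seq.tokens[pos]), seq_vocab)}\t"
                f"{_token_str(int(prot.struct.tokens[pos]), struct_vocab)}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_token_table(
    path: str | Path, seq_vocab: Vocabulary, struct_vocab: Vocabulary
) -> tuple[list[str], list[ProteinTokens]]:
    """Read a token table back into proteins (masks allowed)."""
    rows: dict[str, list[tuple[int, int, int]]] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("protein\t"):
            continue
        pid, pos, s_tok, r_tok = line.split("\t")
        s = seq_vocab.mask_index if s_tok == MASK_CHAR else seq_vocab.index(s_tok)
        r = struct_vocab.mask_index if r_tok == MASK_CHAR else struct_vocab.index(r_tok)
        if pid not in rows:
            rows[pid] = []
            order.append(pid)
        rows[pid].append((int(pos), s, r))
    proteins = []
    for pid in order:
        entries = sorted(rows[pid])
        proteins.append(
            ProteinTokens.from_arrays(
                [e[1] for e in entries], [e[2] for e in entries]
            )
        )
    return order, proteins


def write_fasta(
    path: str | Path,
    tracks: Sequence[TokenTrack],
    vocab: Vocabulary,
    ids: Optional[Sequence[str]] = None,
    descriptions: Optional[Sequence[str]] = None,
) -> None:
    """Export sequence tracks as FASTA (60-column wrap, Biopython)."""
    if ids is None:
        ids = [f"p{i:05d}" for i in range(len(tracks))]
    records = []
    for i, (pid, track) in enumerate(zip(ids, tracks)):
        letters = "".join(_token_str(int(tok), vocab) for tok in track.tokens)
        desc = descriptions[i] if descriptions else ""
        records.append(SeqRecord(Seq(letters), id=pid, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(
    path: str | Path, vocab: Vocabulary, modality: str = SEQUENCE
) -> tuple[list[str], list[TokenTrack]]:
    ids, tracks = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = [
            vocab.mask_index if ch == MASK_CHAR else vocab.index(ch)
            for ch in str(rec.seq)
        ]
        ids.append(rec.id)
        tracks.append(TokenTrack(np.asarray(tokens, dtype=np.int64), modality))
    return ids, tracks


def write_trajectory(
    path: str | Path,
    traj: Trajectory,
    seed: int = 0,
    config: Optional[Mapping[str, object]] = None,
) -> None:
    """Line-delimited JSON: one header object, then one object per step
    with t, token ids per track and realised-token probabilities."""
    with open(path, "w") as fh:
        fh.write(
            json.dumps(
                {
                    "pairflow": __version__,
                    "seed": seed,
                    "config_hash": config_hash(config or {}),
                    "x0_seq": traj.x0.seq.tokens.tolist(),
                    "x0_struct": traj.x0.struct.tokens.tolist(),
                    "cond_seq": traj.cond.seq.astype(int).tolist(),
                    "cond_struct": traj.cond.struct.astype(int).tolist(),
                }
            )
            + "\n"
        )
        for rec in traj.steps:
            fh.write(
                json.dumps(
                    {
                        "t": rec.t,
                        "seq": rec.seq_tokens.tolist(),
                        "struct": rec.struct_tokens.tolist(),
                        "seq_prob": _round_list(rec.seq_token_prob),
                        "struct_prob": _round_list(rec.struct_token_prob),
                        "seq_pred_entropy": _round_list(rec.seq_pred_entropy),
                        "struct_pred_entropy": _round_list(rec.struct_pred_entropy),
                    }
                )
                + "\n"
            )


def _round_list(arr: np.ndarray, digits: int = 6) -> list:
    return [None if np.isnan(v) else round(float(v), digits) for v in arr]


def read_trajectory(path: str | Path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    head = json.loads(lines[0])
    x0 = ProteinTokens.from_arrays(head["x0_seq"], head["x0_struct"])
    cond = ConditionMask(
        np.asarray(head["cond_seq"], dtype=bool),
        np.asarray(head["cond_struct"], dtype=bool),
    )
    steps = []
    for line in lines[1:]:
        obj = json.loads(line)

        def arr(key: str) -> np.ndarray:
            return np.asarray(
                [np.nan if v is None else v for v in obj[key]], dtype=np.float64
            )

        steps.append(
            StepRecord(
                t=obj["t"],
                seq_tokens=np.asarray(obj["seq"], dtype=np.int64),
                struct_tokens=np.asarray(obj["struct"], dtype=np.int64),
                seq_token_prob=arr("seq_prob"),
                struct_token_prob=arr("struct_prob"),
                seq_pred_entropy=arr("seq_pred_entropy"),
                struct_pred_entropy=arr("struct_pred_entropy"),
            )
        )
    return Trajectory(x0=x0, cond=cond, steps=tuple(steps))


def write_world_params(
    path: str | Path, params: ToyWorldParams, seed: Optional[int] = None
) -> None:
    doc = {
        "pairflow": __version__,
        "seed": int(params.seed if seed is None else seed),
        "n_hidden": params.n_hidden,
        "trans": params.trans.tolist(),
        "emit_seq": params.emit_seq.tolist(),
        "emit_struct": params.emit_struct.tolist(),
        "init": params.init.tolist(),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_world_params(path: str | Path) -> ToyWorldParams:
    doc = yaml.safe_load(Path(path).read_text())
    return ToyWorldParams(
        trans=np.asarray(doc["trans"]),
        emit_seq=np.asarray(doc["emit_seq"]),
        emit_struct=np.asarray(doc["emit_struct"]),
        init=np.asarray(doc["init"]),
        seed=int(doc.get("seed", 0)),
    )


def write_loss_trace(
    path: str | Path, trace: np.ndarray, seed: int, config: Mapping[str, object]
) -> None:
    lines = header_lines(seed, config)
    lines.append("epoch,mean_loss")
    for i, v in enumerate(trace):
        lines.append(f"{i + 1},{v:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_reports_csv(
    path: str | Path, reports: Sequence[MetricReport], seed: int = 0
) -> None:
    """Flat CSV of metric reports with their config snapshots as JSON."""
    frame = pd.DataFrame(
        [
            {
                "name": r.name,
                "value": r.value,
                "n": r.n,
                "dispersion": r.dispersion,
                "config": json.dumps(dict(r.config), sort_keys=True, default=str),
            }
            for r in reports
        ]
    )
    with open(path, "w") as fh:
        for line in header_lines(seed, {"reports": [r.name for r in reports]}):
            fh.write(line + "\n")
        frame.to_csv(fh, index=False)


def parse_motif_positions(text: str) -> frozenset[int]:
    """Parse comma-separated 0-based positions/ranges, e.g. '2-3,7'."""
    out: set[int] = set()
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            lo, hi = chunk.split("-")
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(chunk))
    if not out:
        raise ValueError(f"no positions in {text!r}")
    return frozenset(out)
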