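"""Format readers/writers, run manifests and small report helpers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_states_tsv",
    "write_tsv",
    "write_json",
    "RunManifest",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA records as an ordered {id: uppercase sequence} mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70):
    lines = []
    for name, seq in seqs.items():
        lines.append(f">{name}")
        lines += [seq[i:i + width] for i in range(0, len(seq), width)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_states_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (species, state) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    return dict(zip(df[0].astype(str), df[1].astype(str)))


def write_tsv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every output bundle."""

    command: str
    seed: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    config_hash: str = ""
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @classmethod
    def collect(
        cls,
        command: str,
        input_paths: dict[str, str | Path],
        seed: int | None = None,
        config_text: str = "",
    ) -> "RunManifest":
        return cls(
            command=command,
            seed=seed,
            inputs={
                name: _checksum(Path(p))
                for name, p in input_paths.items()
                if p is not None and Path(p).exists()
            },
            config_hash=hashlib.sha256(
                config_text.encode()
            ).hexdigest()[:16]
            if config_text
            else "",
        )

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        write_json(asdict(self), path)
        return path
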