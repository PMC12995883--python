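"""Readers/writers binding the pipeline stages together.

Interchange formats: one UTF-8 ``.txt`` per note, JSONL for gold labels,
structured records and decision logs, YAML for run configuration, and a JSON
manifest (tool version, config hash, seeds) written next to every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence

import yaml

from . import __version__
from .records import ClinicalNote, GoldRecord, StructuredRecord


class DataFormatError(ValueError):
    pass


def write_notes(notes: Sequence[ClinicalNote], directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for note in notes:
        (directory / f"{note.case_id}.txt").write_text(note.text, encoding="utf-8")


def read_notes(directory: Path, language: str = "en") -> Iterator[ClinicalNote]:
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"notes directory not found: {directory}")
    for path in sorted(directory.glob("*.txt")):
        yield ClinicalNote(
            case_id=path.stem, text=path.read_text(encoding="utf-8"), language=language
        )


def write_jsonl(records: Sequence[dict], path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_jsonl(path: Path) -> List[dict]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                out.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise DataFormatError(f"{path}:{lineno}: malformed JSONL line") from exc
    return out


def write_gold(golds: Sequence[GoldRecord], path: Path) -> None:
    write_jsonl([g.as_dict() for g in golds], path)


def read_gold(path: Path) -> List[GoldRecord]:
    return [GoldRecord.from_dict(d) for d in read_jsonl(path)]


def write_records(records: Sequence[StructuredRecord], case_ids: Sequence[str], path: Path) -> None:
    rows = []
    for cid, rec in zip(case_ids, records):
        row = {"case_id": cid}
        row.update(rec.as_dict())
        rows.append(row)
    write_jsonl(rows, path)


def read_records(path: Path) -> Dict[str, StructuredRecord]:
    out = {}
    for row in read_jsonl(path):
        row = dict(row)
        cid = row.pop("case_id")
        out[cid] = StructuredRecord.from_dict(row)
    return out


def load_yaml_config(path: Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise DataFormatError(f"configuration file {path} must hold a mapping")
    return data


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, ensure_ascii=False, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def write_manifest(path: Path, config: dict, seeds: Dict[str, int]) -> None:
    """Reproducibility manifest written alongside every output artifact."""
    manifest = {
        "tool": "hepadecide",
        "version": __version__,
        "config_hash": config_hash(config),
        "seeds": seeds,
        "config": config,
    }
    Path(path).write_text(
        json.dumps(manifest, indent=2, ensure_ascii=False, default=str), encoding="utf-8"
    )
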