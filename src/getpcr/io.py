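"""File formats: FASTA loci, delimited Ct tables and guide specs, JSON assay
bundles and truth records, YAML penalty models.

Ct tables are long format (one measurement per row) to match instrument
exports and keep replicate structure explicit.  Assay bundles embed primer
coordinates so quantification never re-derives design decisions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from Bio import SeqIO

from .errors import SchemaError, ValidationError
from .mismatch import PenaltyModel
from .primerdesign import Primer, PrimerAssay
from .quant import REQUIRED_COLUMNS, CtTable
from .seqmodel import TargetLocus

#: Ct strings mapped to the no-amplification sentinel
NO_AMP_STRINGS = {"", "NA", "N/A", "NAN", "UNDETERMINED", "ND", "NOAMP", "NO_AMP"}


def read_fasta(path) -> list[TargetLocus]:
    """Parse a single- or multi-record FASTA into validated loci."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SchemaError(f"{path}: no FASTA records found")
    loci = []
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise SchemaError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            loci.append(TargetLocus(rec.id, seq))
        except ValidationError as exc:
            raise SchemaError(f"{path}: record {rec.id!r}: {exc}") from None
    return loci


def write_fasta(loci, path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(f">{locus.id}\n")
            seq = locus.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")


def read_ct_table(path) -> CtTable:
    """Read a delimited (comma or tab) long-format Ct table.

    Required header: sample_id, assay_id, channel, replicate, ct.  Sentinel
    strings such as ``NA`` or ``Undetermined`` become the no-amplification
    value; any other non-numeric Ct is an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         keep_default_na=False)
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse delimited text: {exc}") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    def to_ct(value: str) -> float:
        if value.strip().upper() in NO_AMP_STRINGS:
            return float("nan")
        try:
            return float(value)
        except ValueError:
            raise SchemaError(f"{path}: non-numeric Ct value {value!r}") from None

    df = df.copy()
    df["ct"] = df["ct"].map(to_ct)
    try:
        return CtTable(df)
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_ct_table(table: CtTable, path) -> None:
    df = table.df.copy()
    df["ct"] = df["ct"].map(lambda v: "Undetermined" if pd.isna(v) else f"{v:.4f}")
    df.to_csv(path, index=False)


def read_guides(path) -> list[dict]:
    """Guide specification table: columns locus_id, protospacer and optional
    pam (default NGG)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for col in ("locus_id", "protospacer"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if "pam" not in df.columns:
        df["pam"] = "NGG"
    df["pam"] = df["pam"].fillna("NGG")
    return df[["locus_id", "protospacer", "pam"]].to_dict("records")


# ---------------------------------------------------------------------------
# assay bundles

def _primer_to_dict(p: Primer | None):
    return None if p is None else dataclasses.asdict(p)


def _primer_from_dict(d) -> Primer | None:
    return None if d is None else Primer(**d)


def assay_to_dict(assay: PrimerAssay) -> dict:
    return {
        "assay_id": assay.assay_id,
        "mode": assay.mode,
        "watch_forward": _primer_to_dict(assay.watch_forward),
        "watch_reverse": _primer_to_dict(assay.watch_reverse),
        "partner": _primer_to_dict(assay.partner),
        "control_forward": _primer_to_dict(assay.control_forward),
        "control_reverse": _primer_to_dict(assay.control_reverse),
        "recommended_anneal_c": assay.recommended_anneal_c,
        "flags": list(assay.flags),
    }


def assay_from_dict(data: Mapping) -> PrimerAssay:
    return PrimerAssay(
        assay_id=data["assay_id"],
        mode=data["mode"],
        watch_forward=_primer_from_dict(data.get("watch_forward")),
        watch_reverse=_primer_from_dict(data.get("watch_reverse")),
        partner=_primer_from_dict(data.get("partner")),
        control_forward=_primer_from_dict(data.get("control_forward")),
        control_reverse=_primer_from_dict(data.get("control_reverse")),
        recommended_anneal_c=float(data.get("recommended_anneal_c", 0.0)),
        flags=tuple(data.get("flags", ())),
    )


def write_assays(assays: Mapping[str, PrimerAssay], path) -> None:
    payload = {name: assay_to_dict(a) for name, a in assays.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_assays(path) -> dict[str, PrimerAssay]:
    data = json.loads(Path(path).read_text())
    return {name: assay_from_dict(d) for name, d in data.items()}


def primer_report(assays: Mapping[str, PrimerAssay]) -> pd.DataFrame:
    """Flat TSV-ready primer report: one row per primer of every assay."""
    rows = []
    for name, assay in assays.items():
        for slot in ("watch_forward", "watch_reverse", "partner",
                     "control_forward", "control_reverse"):
            p: Primer | None = getattr(assay, slot)
            if p is None:
                continue
            rows.append({
                "assay_id": name, "slot": slot, "sequence": p.sequence,
                "orientation": p.orientation, "three_prime_pos": p.three_prime_pos,
                "length": len(p.sequence), "tm_c": p.tm_c,
                "watching_bases": p.watching_bases,
                "terminal_base": p.terminal_base,
                "anneal_c": assay.recommended_anneal_c,
                "flags": ";".join(assay.flags),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# penalty model and truth records

def write_penalty_model(model: PenaltyModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=True))


def read_penalty_model(path) -> PenaltyModel:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: penalty model must be a mapping")
    return PenaltyModel.from_dict(data)


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def config_hash(payload: Mapping) -> str:
    """Stable hash of a run configuration, for the reproducibility log."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
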