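"""Readers, writers and model serialization.

Peptide tables are tab-separated with a header ``id<TAB>sequence[<TAB>pic50]``;
FASTA is accepted for sequences with targets joined from a separate
``id<TAB>pic50`` table.  Descriptor tables are tab-separated with the
amino-acid one-letter code in the first column and named properties in the
rest.  Fitted models round-trip through a self-contained JSON file
(normalizer statistics, both weight vectors, selection, hyperparameters,
seeds and the descriptor table), so prediction needs nothing but the model
file and the peptides.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .encoders import (
    STANDARD_AA,
    DescriptorTable,
    FeatureMatrix,
    Normalizer,
    PeptideDataset,
)
from .errors import InputError, ModelFormatError
from .objective import LinearModel
from .optimizer import RpropConfig
from .pipeline import RunConfig, TwoStepModel

MODEL_FORMAT_VERSION = 1


def read_peptide_table(path, has_targets: bool = True) -> PeptideDataset:
    """Read a TSV peptide table, validating as it parses.

    Errors cite the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: file not found")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise InputError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header[:2] != ["id", "sequence"]:
        raise InputError(
            f"{path}:1: header must start with 'id<TAB>sequence', "
            f"got {lines[0]!r}"
        )
    has_target_col = len(header) > 2 and header[2] == "pic50"
    if has_targets and not has_target_col:
        raise InputError(f"{path}:1: missing required 'pic50' column")
    ids: list[str] = []
    seqs: list[str] = []
    targets: list[float] = []
    length: int | None = None
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2 + int(has_targets):
            raise InputError(f"{path}:{ln}: expected at least "
                             f"{2 + int(has_targets)} tab-separated fields")
        pid, seq = fields[0], fields[1].upper()
        if pid in ids:
            raise InputError(f"{path}:{ln}: duplicate id {pid!r}")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise InputError(
                f"{path}:{ln}: sequence length {len(seq)} differs from "
                f"{length} seen earlier"
            )
        bad = set(seq) - set(STANDARD_AA + "*BXZ")
        if bad:
            raise InputError(
                f"{path}:{ln}: illegal residue(s) {sorted(bad)} in {seq!r}"
            )
        if has_targets:
            try:
                targets.append(float(fields[2]))
            except ValueError:
                raise InputError(
                    f"{path}:{ln}: non-numeric pic50 value {fields[2]!r}"
                ) from None
        ids.append(pid)
        seqs.append(seq)
    if not ids:
        raise InputError(f"{path}: no peptide records")
    return PeptideDataset(
        ids=ids,
        sequences=seqs,
        targets=np.array(targets) if has_targets else None,
    )


def write_peptide_table(dataset: PeptideDataset, path) -> None:
    with open(path, "w") as fh:
        if dataset.targets is not None:
            fh.write("id\tsequence\tpic50\n")
            for pid, seq, t in zip(
                dataset.ids, dataset.sequences, dataset.targets
            ):
                fh.write(f"{pid}\t{seq}\t{float(t)!r}\n")
        else:
            fh.write("id\tsequence\n")
            for pid, seq in zip(dataset.ids, dataset.sequences):
                fh.write(f"{pid}\t{seq}\n")


def read_fasta_peptides(path, targets_path=None) -> PeptideDataset:
    """Read peptides from FASTA, optionally joining targets on id."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: file not found")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    targets = None
    if targets_path is not None:
        tmap = _read_target_table(targets_path)
        missing = [i for i in ids if i not in tmap]
        if missing:
            raise InputError(
                f"{targets_path}: no target for id(s) {missing[:5]}"
            )
        targets = np.array([tmap[i] for i in ids])
    return PeptideDataset(ids=ids, sequences=seqs, targets=targets)


def _read_target_table(path) -> dict[str, float]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: file not found")
    out: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if ln == 1 and fields[0] in ("id", "#id"):
                continue
            if len(fields) < 2:
                raise InputError(f"{path}:{ln}: expected 'id<TAB>pic50'")
            try:
                out[fields[0]] = float(fields[1])
            except ValueError:
                raise InputError(
                    f"{path}:{ln}: non-numeric value {fields[1]!r}"
                ) from None
    return out


def read_descriptor_table(path) -> DescriptorTable:
    """Read a TSV amino-acid descriptor table (20 rows, named properties)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: file not found")
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, float_precision="round_trip"
        )
    except Exception as exc:
        raise InputError(f"{path}: cannot parse descriptor table: {exc}")
    missing = [aa for aa in STANDARD_AA if aa not in df.index]
    if missing:
        raise InputError(f"{path}: missing amino acid row(s) {missing}")
    values = {}
    for aa in STANDARD_AA:
        row = pd.to_numeric(df.loc[aa], errors="coerce")
        if row.isna().any():
            bad = df.loc[aa][row.isna()].index.tolist()
            raise InputError(
                f"{path}: non-numeric value(s) for {aa!r} in column(s) {bad}"
            )
        values[aa] = row.to_numpy(dtype=float)
    return DescriptorTable(
        property_names=[str(c) for c in df.columns], values=values
    )


def write_descriptor_table(table: DescriptorTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("aa\t" + "\t".join(table.property_names) + "\n")
        for aa in STANDARD_AA:
            vals = "\t".join(repr(float(v)) for v in table.values[aa])
            fh.write(f"{aa}\t{vals}\n")


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(matrix.feature_names) + "\n")
        for row in matrix.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def write_predictions(ids, predictions, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tpredicted_pic50\n")
        for pid, p in zip(ids, predictions):
            fh.write(f"{pid}\t{float(p)!r}\n")


def read_predictions(path) -> dict[str, float]:
    return _read_target_table(path)


def save_model(model: TwoStepModel, path) -> None:
    """Serialize a fitted model to self-contained JSON."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "peptide_length": model.peptide_length,
        "lambda1": model.lambda1,
        "lambda2": model.lambda2,
        "threshold": model.threshold,
        "normalizer": {
            "kept_indices": model.normalizer.kept_indices.tolist(),
            "means": model.normalizer.means.tolist(),
            "sds": model.normalizer.sds.tolist(),
        },
        "stage1": {"w": model.stage1.w.tolist(), "b": model.stage1.b},
        "selected_indices": model.selected_indices.tolist(),
        "stage2": {"w": model.stage2.w.tolist(), "b": model.stage2.b},
        "feature_names": model.feature_names,
        "selected_feature_names": model.selected_feature_names,
        "descriptor_table": {
            "property_names": model.table.property_names,
            "values": {
                aa: model.table.values[aa].tolist() for aa in STANDARD_AA
            },
        },
        "config": {
            "lambda1_grid": list(model.config.lambda1_grid),
            "lambda2_grid": list(model.config.lambda2_grid),
            "k_repeats": model.config.k_repeats,
            "n_folds": model.config.n_folds,
            "threshold": model.config.threshold,
            "seed": model.config.seed,
            "loss": model.config.loss,
            "normalization": model.config.normalization,
            "validation_metric": model.config.validation_metric,
            "rprop": {
                "eta_plus": model.config.rprop.eta_plus,
                "eta_minus": model.config.rprop.eta_minus,
                "delta0": model.config.rprop.delta0,
                "delta_min": model.config.rprop.delta_min,
                "delta_max": model.config.rprop.delta_max,
                "max_iter": model.config.rprop.max_iter,
                "tol": model.config.rprop.tol,
            },
        },
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TwoStepModel:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: file not found")
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid model JSON: {exc}")
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format version {version!r}"
        )
    try:
        table = DescriptorTable(
            property_names=payload["descriptor_table"]["property_names"],
            values={
                aa: np.array(v)
                for aa, v in payload["descriptor_table"]["values"].items()
            },
        )
        cfg_raw = payload["config"]
        config = RunConfig(
            lambda1_grid=tuple(cfg_raw["lambda1_grid"]),
            lambda2_grid=tuple(cfg_raw["lambda2_grid"]),
            k_repeats=cfg_raw["k_repeats"],
            n_folds=cfg_raw["n_folds"],
            threshold=cfg_raw["threshold"],
            seed=cfg_raw["seed"],
            loss=cfg_raw["loss"],
            normalization=cfg_raw["normalization"],
            validation_metric=cfg_raw["validation_metric"],
            rprop=RpropConfig(**cfg_raw["rprop"]),
        )
        return TwoStepModel(
            normalizer=Normalizer(
                kept_indices=np.array(
                    payload["normalizer"]["kept_indices"], dtype=int
                ),
                means=np.array(payload["normalizer"]["means"]),
                sds=np.array(payload["normalizer"]["sds"]),
            ),
            stage1=LinearModel(
                w=np.array(payload["stage1"]["w"]), b=payload["stage1"]["b"]
            ),
            selected_indices=np.array(
                payload["selected_indices"], dtype=int
            ),
            stage2=LinearModel(
                w=np.array(payload["stage2"]["w"]), b=payload["stage2"]["b"]
            ),
            lambda1=payload["lambda1"],
            lambda2=payload["lambda2"],
            threshold=payload["threshold"],
            peptide_length=payload["peptide_length"],
            feature_names=payload["feature_names"],
            table=table,
            config=config,
            provenance=payload.get("provenance", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: malformed model file: {exc}")
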