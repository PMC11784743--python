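"""File formats: feature tables (CSV), model checkpoints, configs, manifests.

The interchange format for multimodal feature data is a plain delimited text
table with a header row: mandatory ``subject`` and ``label`` columns (labels
serialized as class names), an optional ``session`` column, then the EEG and
non-EEG feature columns in schema order. Checkpoints are single-file numpy
archives carrying both parameter sets, the specs, scaler states, variant tag
and a schema hash that is verified on load.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (FeatureSchema, MultimodalDataset, ScalerState, get_profile)
from .gan import (Discriminator, DiscriminatorSpec, Generator, GeneratorSpec,
                  HatlModel, TrainConfig)

__all__ = [
    "write_feature_table",
    "read_feature_table",
    "save_checkpoint",
    "load_checkpoint",
    "load_train_config",
    "RunManifest",
]

META_COLUMNS = ("subject", "label", "session")


class TableFormatError(ValueError):
    pass


def write_feature_table(ds: MultimodalDataset, path) -> None:
    cols = {"subject": ds.subject,
            "label": [ds.schema.label_scheme.class_names[i] for i in ds.y]}
    if ds.session is not None:
        cols["session"] = ds.session
    frame = pd.DataFrame(cols)
    eeg = pd.DataFrame(ds.X_eeg, columns=list(ds.schema.eeg_feature_names))
    noneeg = pd.DataFrame(ds.S_noneeg, columns=list(ds.schema.noneeg_features))
    pd.concat([frame, eeg, noneeg], axis=1).to_csv(path, index=False)


def read_feature_table(path, schema: FeatureSchema,
                       strict: bool = True) -> MultimodalDataset:
    """Parse a feature table against a schema.

    Strict mode requires exactly the schema's feature columns in schema
    order; permissive mode ignores unknown columns.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("subject", "label"):
        if col not in frame.columns:
            raise TableFormatError(f"missing mandatory column {col!r} in {path}")
    expected = list(schema.eeg_feature_names) + list(schema.noneeg_features)
    feature_cols = [c for c in frame.columns if c not in META_COLUMNS]
    if strict:
        if feature_cols != expected:
            missing = set(expected) - set(feature_cols)
            extra = set(feature_cols) - set(expected)
            raise TableFormatError(
                f"feature columns do not match schema {schema.name!r} "
                f"(missing: {sorted(missing)}, unknown: {sorted(extra)})")
    else:
        absent = [c for c in expected if c not in frame.columns]
        if absent:
            raise TableFormatError(f"missing feature columns: {absent}")
    values = frame[expected]
    bad = values.map(lambda v: isinstance(v, str))
    if bad.any().any():
        r = int(np.argwhere(bad.values)[0][0])
        c = bad.columns[int(np.argwhere(bad.values)[0][1])]
        raise TableFormatError(f"non-numeric cell at row {r}, column {c!r}")
    names = list(schema.label_scheme.class_names)
    try:
        y = np.array([names.index(v) for v in frame["label"]])
    except ValueError as e:
        raise TableFormatError(f"label outside scheme: {e}") from None
    session = frame["session"].to_numpy() if "session" in frame.columns else None
    return MultimodalDataset(
        X_eeg=values[list(schema.eeg_feature_names)].to_numpy(float),
        S_noneeg=values[list(schema.noneeg_features)].to_numpy(float),
        y=y, subject=frame["subject"].to_numpy(), schema=schema,
        session=session)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def _scaler_arrays(prefix: str, s: ScalerState | None) -> dict:
    if s is None:
        return {}
    return {f"{prefix}_mins": s.mins, f"{prefix}_maxs": s.maxs}


def save_checkpoint(model: HatlModel, path) -> None:
    meta = {
        "format": "hatl-checkpoint-v1",
        "variant": model.variant,
        "schema_hash": model.schema_hash,
        "n_classes": model.n_classes,
        "trained": model.trained,
        "gen_spec": asdict(model.gen_spec),
        "disc_spec": asdict(model.disc_spec),
        "config": asdict(model.config),
        "history": model.history,
    }
    arrays = {**model.generator.state_arrays(),
              **model.discriminator.state_arrays(),
              **_scaler_arrays("eeg_scaler", model.eeg_scaler),
              **_scaler_arrays("noneeg_scaler", model.noneeg_scaler)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path, expect_schema: FeatureSchema | None = None,
                    expect_variant: str | None = None) -> HatlModel:
    try:
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            if meta.get("format") != "hatl-checkpoint-v1":
                raise ValueError("not a recognised checkpoint file")
            arrays = {k: archive[k] for k in archive.files if k != "meta"}
    except (OSError, KeyError, json.JSONDecodeError, ValueError) as e:
        raise ValueError(f"corrupted or invalid checkpoint {path}: {e}") from e
    if expect_variant is not None and meta["variant"] != expect_variant:
        raise ValueError(f"checkpoint holds a {meta['variant']} model, "
                         f"expected {expect_variant}")
    if expect_schema is not None and meta["schema_hash"] != expect_schema.hash():
        raise ValueError("checkpoint schema hash does not match the dataset schema")
    gen_spec = GeneratorSpec(**{k: tuple(v) if isinstance(v, list) else v
                                for k, v in meta["gen_spec"].items()})
    disc_spec = DiscriminatorSpec(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in meta["disc_spec"].items()})
    cfg = meta["config"]
    cfg["betas"] = tuple(cfg["betas"])
    config = TrainConfig(**cfg)
    rng = np.random.default_rng(0)  # weights are overwritten below
    gen = Generator(gen_spec, rng)
    disc = Discriminator(disc_spec, rng)
    gen.load_state_arrays(arrays)
    disc.load_state_arrays(arrays)

    def scaler(prefix):
        if f"{prefix}_mins" not in arrays:
            return None
        return ScalerState(arrays[f"{prefix}_mins"], arrays[f"{prefix}_maxs"])

    return HatlModel(
        variant=meta["variant"], generator=gen, discriminator=disc,
        gen_spec=gen_spec, disc_spec=disc_spec, config=config,
        schema_hash=meta["schema_hash"], n_classes=meta["n_classes"],
        trained=meta["trained"], history=meta["history"],
        eeg_scaler=scaler("eeg_scaler"), noneeg_scaler=scaler("noneeg_scaler"))


def load_train_config(path=None, **overrides) -> TrainConfig:
    """TrainConfig from a YAML file, with keyword overrides taking precedence."""
    values = {}
    if path is not None:
        with open(path) as fh:
            values.update(yaml.safe_load(fh) or {})
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "betas" in values:
        values["betas"] = tuple(values["betas"])
    return TrainConfig(**values)


@dataclass
class RunManifest:
    """Provenance record written next to every CLI stage's outputs."""

    stage: str
    seed: int
    profile: str
    schema_hash: str
    outputs: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    wall_clock_s: float = 0.0

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class StageTimer:
    def __enter__(self):
        self.t0 = time.monotonic()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.monotonic() - self.t0
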