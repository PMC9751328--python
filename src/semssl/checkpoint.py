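"""Self-describing checkpoints for encoder states and classifier heads.

Stored as NumPy ``.npz`` archives: every parameter under its qualified
name, plus a JSON-encoded header with the variant, architecture and seed
so a checkpoint can be rebuilt without the config that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import numpy as np

from . import nn
from .downstream import BinaryClassifier
from .ssl import EncoderState, NegativeQueue
from .types import ClassLabel, CLASS_ORDER

PathLike = Union[str, Path]


def save_state(state: EncoderState, path: PathLike) -> None:
    arrays: Dict[str, np.ndarray] = {}
    for k, v in state.query_params().items():
        arrays[f"query/{k}"] = v
    if state.momentum_encoder is not None:
        for k, v in state.momentum_params().items():
            arrays[f"momentum/{k}"] = v
        arrays["queue/keys"] = state.queue.keys
    header = {
        "variant": state.variant,
        "momentum_coefficient": state.momentum_coefficient,
        "temperature": state.temperature,
        "lambda_bt": state.lambda_bt,
        "queue_capacity": state.queue.capacity if state.queue else 0,
        "config": state.config,
    }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_state(path: PathLike) -> EncoderState:
    from .ssl import PretrainConfig, init_state

    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        cfg = PretrainConfig(
            encoder_channels=tuple(header["config"].get("encoder_channels",
                                                        (8, 16, 32, 64))),
            projector_dim=header["config"].get("projector_dim", 64),
            projector_hidden=header["config"].get("projector_hidden", 128),
            temperature=header["temperature"],
            momentum_coefficient=header["momentum_coefficient"],
            lambda_bt=header["lambda_bt"],
            queue_capacity=max(1, header["queue_capacity"]),
            seed=header["config"].get("seed", 0))
        state = init_state(header["variant"], cfg)
        q = {k[len("query/"):]: data[k] for k in data.files
             if k.startswith("query/")}
        _load_split(state.encoder, state.projector, q)
        if header["variant"] == "contrastive":
            m = {k[len("momentum/"):]: data[k] for k in data.files
                 if k.startswith("momentum/")}
            _load_split(state.momentum_encoder, state.momentum_projector, m)
            state.queue = NegativeQueue(header["queue_capacity"],
                                        data["queue/keys"].shape[1])
            state.queue.keys = data["queue/keys"]
    return state


def _load_split(encoder: nn.Module, projector: nn.Module,
                flat: Dict[str, np.ndarray]) -> None:
    encoder.load_state_dict({k[len("encoder."):]: v for k, v in flat.items()
                             if k.startswith("encoder.")})
    projector.load_state_dict({k[len("projector."):]: v for k, v in flat.items()
                               if k.startswith("projector.")})


def save_heads(models: Dict[ClassLabel, BinaryClassifier], path: PathLike) -> None:
    arrays: Dict[str, np.ndarray] = {}
    meta = {}
    for label, clf in models.items():
        tag = label.name.lower()
        for k, v in clf.encoder.state_dict().items():
            arrays[f"{tag}/encoder/{k}"] = v
        for k, v in clf.head.state_dict().items():
            arrays[f"{tag}/head/{k}"] = v
        meta[tag] = {"output_size": clf.output_size,
                     "input_mode": clf.input_mode,
                     "channels": [c.weight.data.shape[0]
                                  for c in clf.encoder.convs]}
    arrays["header"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_heads(path: PathLike) -> Dict[ClassLabel, BinaryClassifier]:
    models: Dict[ClassLabel, BinaryClassifier] = {}
    with np.load(path) as data:
        meta = json.loads(bytes(data["header"]).decode())
        for label in CLASS_ORDER:
            tag = label.name.lower()
            if tag not in meta:
                continue
            encoder = nn.ConvEncoder(tuple(meta[tag]["channels"]))
            encoder.load_state_dict(
                {k.split("/", 2)[2]: data[k] for k in data.files
                 if k.startswith(f"{tag}/encoder/")})
            head = nn.Linear(encoder.out_dim, 1)
            head.load_state_dict(
                {k.split("/", 2)[2]: data[k] for k in data.files
                 if k.startswith(f"{tag}/head/")})
            models[label] = BinaryClassifier(
                encoder, head, label, meta[tag]["output_size"],
                meta[tag]["input_mode"])
    return models
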