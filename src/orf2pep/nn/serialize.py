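"""Deterministic model checkpoint I/O.

Checkpoints are zip archives holding a JSON manifest (format version,
user-supplied config) plus one ``.npy`` member per weight/buffer.  All zip
member timestamps are pinned so that identical models serialize to
byte-identical files.
"""

from __future__ import annotations

import io
import json
import zipfile

import numpy as np

FORMAT_VERSION = 1
_EPOCH = (1980, 1, 1, 0, 0, 0)


def save_checkpoint(path, state: dict, config: dict, kind: str):
    manifest = {
        "format_version": FORMAT_VERSION,
        "kind": kind,
        "config": config,
        "arrays": sorted(state.keys()),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo("manifest.json", date_time=_EPOCH)
        zf.writestr(info, json.dumps(manifest, sort_keys=True, indent=1))
        for name in sorted(state.keys()):
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.ascontiguousarray(state[name]))
            info = zipfile.ZipInfo(f"arrays/{name}.npy", date_time=_EPOCH)
            zf.writestr(info, buf.getvalue())


def load_checkpoint(path, expect_kind: str | None = None):
    with zipfile.ZipFile(path, "r") as zf:
        manifest = json.loads(zf.read("manifest.json"))
        version = manifest.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"incompatible checkpoint format version {version!r} "
                f"(this build reads version {FORMAT_VERSION})")
        if expect_kind is not None and manifest.get("kind") != expect_kind:
            raise ValueError(
                f"checkpoint holds a {manifest.get('kind')!r} model, "
                f"expected {expect_kind!r}")
        state = {}
        for name in manifest["arrays"]:
            with zf.open(f"arrays/{name}.npy") as fh:
                state[name] = np.lib.format.read_array(fh)
    return state, manifest["config"], manifest["kind"]
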