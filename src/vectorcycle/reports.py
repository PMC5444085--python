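"""JSON/CSV report writers, output validation and run manifests.

Every CLI run emits one manifest recording the tool version, a hash of
the configuration, the seed and the files read and written, so a result
file can always be traced back to the exact inputs that produced it.
JSON reports keep full double precision; all probability-like fields are
checked to lie in [0, 1] before anything is written.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import math
from pathlib import Path

from vectorcycle.errors import ValidationError

#: Report keys whose numeric values (or numeric list/dict members) must be
#: probabilities.
_PROB_PREFIXES = (
    "p_",
    "pi_",
    "q_",
    "f_",
    "c_m",
    "coverage",
    "pre_kill",
    "block",
    "post_kill",
    "estimate",
    "ci_",
    "residual_meal",
    "r_indoor",
    "sugar_rate",
)


def _is_prob_key(key: str) -> bool:
    return any(key.startswith(p) for p in _PROB_PREFIXES)


def _check_probs(obj, key: str = "") -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _check_probs(v, k if isinstance(k, str) else key)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            _check_probs(v, key)
    elif isinstance(obj, (int, float)) and not isinstance(obj, bool):
        if _is_prob_key(key):
            if not math.isfinite(obj) or obj < -1e-12 or obj > 1.0 + 1e-12:
                raise ValidationError(
                    f"report field {key!r} = {obj!r} is not a probability"
                )


def write_json_report(obj: dict, path: str | Path) -> Path:
    """Validate probability fields and write a JSON report."""
    _check_probs(obj)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def config_hash(path: str | Path | None) -> str | None:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    outdir: str | Path,
    command: str,
    seed: int | None,
    config_path: str | Path | None,
    inputs: list[str],
    outputs: list[str],
    name: str = "manifest.json",
) -> Path:
    from vectorcycle import __version__

    manifest = {
        "tool": "vectorcycle",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config_sha256": config_hash(config_path),
        "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(p) for p in outputs),
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
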