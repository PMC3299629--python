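"""Packaged fixtures and result serialization helpers."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .fitting import FitDataset
from .params import ModelParams, save_params
from .protocols import HabituationCurve, IORCurve
from .simulate import TrialResult

__all__ = ["load_fixture", "load_protocol", "write_trial_result", "write_curve"]

_DATA = Path(__file__).parent / "data"

#: observed IOR increments, approximate values read off the cueing study's
#: published figure (the exact numbers were never printed)
_FIXTURES = {
    "posner_cohen_inhibition": {
        "path": _DATA / "posner_cohen_inhibition_digitized.csv",
        "note": (
            "Approximate digitization of the observed cued-minus-uncued RT "
            "increments for CTOAs 0-500 ms; anchored to the reported 21 ms "
            "facilitation at CTOA 0, a facilitation-to-inhibition crossover "
            "between 200 and 300 ms, and late inhibition of about 15 ms."
        ),
    },
}


def load_fixture(name: str = "posner_cohen_inhibition") -> FitDataset:
    """Load a packaged observed-inhibition dataset.

    The shipped fixture is flagged ``approximate``: it is a digitized
    estimate, not published numbers.
    """
    try:
        entry = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return FitDataset.from_csv(entry["path"], approximate=True, note=entry["note"])


def load_protocol(name: str = "posner_cohen") -> dict:
    """Load a shipped trial-layout file (nodes, CTOAs, stimulus constants).

    Numeric stimulus constants are stored as decimal strings for provenance
    and returned as floats.
    """
    path = _DATA / f"{name}_protocol.yaml"
    if not path.exists():
        raise KeyError(f"unknown protocol {name!r}")
    raw = yaml.safe_load(path.read_text())

    def _floats(d):
        return {
            k: (float(v) if isinstance(v, str) else _floats(v) if isinstance(v, dict) else v)
            for k, v in d.items()
        }

    return _floats(raw)


def write_trial_result(result: TrialResult, outdir: str | Path, stem: str = "trial") -> None:
    """Write a trial's summary JSON and, when recorded, its trace CSV.

    The trace schema is long-format: time, node, D, S, H, a_D, a_S.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "responded": result.responded,
        "rt_ms": result.rt,
        "crossing_time_ms": result.crossing_time,
        "crossing_node": result.crossing_node,
        "peak_target_rate": result.peak_target_rate,
    }
    (outdir / f"{stem}_summary.json").write_text(json.dumps(summary, indent=2))
    if result.traces is not None:
        tr = result.traces
        n = tr["D"].shape[1]
        frames = []
        for i in range(n):
            frames.append(
                pd.DataFrame(
                    {
                        "time": tr["t"],
                        "node": i + 1,
                        "D": tr["D"][:, i],
                        "S": tr["S"][:, i],
                        "H": tr["H"][:, i],
                        "a_D": tr["a_D"][:, i],
                        "a_S": tr["a_S"][:, i],
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / f"{stem}_traces.csv", index=False
        )


def write_curve(curve: IORCurve | HabituationCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def echo_params(params: ModelParams, outdir: str | Path) -> None:
    """Write the exact parameter set used into an output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_params(params, outdir / "params_used.yaml")
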