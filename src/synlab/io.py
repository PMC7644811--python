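"""Reading and writing trial data.

Fixtures travel as plain CSV (wide matrix, first column time in
seconds, one column per muscle) with an optional JSON sidecar holding
metadata and generator truth. Public locomotor-EMG deposits shipped
as RData lists (raw EMG, cycle times and extracted synergies, keyed
by participant/condition trial names) can be read when the optional
``pyreadr`` dependency is installed.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .datatypes import GaitCycleTimes, MUSCLES, RawEmgRecording, TrialMeta

_KEY_RE = re.compile(
    r"^(?P<prefix>[A-Z_]+?)_?P(?P<participant>\d{4})_"
    r"(?P<environment>[OT])(?P<locomotion>[WR])_(?P<trial>\d{2})$"
)


def parse_trial_key(key: str) -> dict:
    """Parse a deposit trial key like ``CYCLE_TIMES_P0020_TW_01``.

    The two-letter condition code stores the environment first
    (O = overground, T = treadmill) and the locomotion type second
    (W = walking, R = running).
    """
    m = _KEY_RE.match(key.strip())
    if m is None:
        raise ValueError(f"unparseable trial key: {key!r}")
    d = m.groupdict()
    return {
        "prefix": d["prefix"].rstrip("_"),
        "participant": f"P{d['participant']}",
        "environment": d["environment"],
        "locomotion": d["locomotion"],
        "trial": int(d["trial"]),
    }


def write_trial_csv(raw: RawEmgRecording, path: str | Path) -> Path:
    """Write a recording as a wide CSV (time + 13 muscle columns)."""
    path = Path(path)
    t = np.arange(raw.n_samples) / raw.fs
    df = pd.DataFrame({"time": t})
    for i, muscle in enumerate(raw.muscles):
        df[muscle] = raw.samples[i]
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trial_csv(path: str | Path, meta: Optional[TrialMeta] = None) -> RawEmgRecording:
    """Read a wide trial CSV, coercing channels to canonical order.

    The sampling rate is inferred from the time column, which must be
    uniform to within 1 ppm.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "time" not in df.columns:
        raise ValueError(f"{path}: missing 'time' column")
    missing = [m for m in MUSCLES if m not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing muscle column(s): {', '.join(missing)}")
    t = df["time"].to_numpy()
    dt = np.diff(t)
    if dt.size < 1 or np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    mean_dt = dt.mean()
    if np.max(np.abs(dt - mean_dt)) > 1e-6 * mean_dt:
        raise ValueError(f"{path}: non-uniform sampling beyond 1 ppm")
    samples = np.vstack([df[m].to_numpy() for m in MUSCLES])
    return RawEmgRecording(samples=samples, fs=1.0 / mean_dt, meta=meta)


def write_cycle_times_csv(events: GaitCycleTimes, path: str | Path) -> Path:
    """Write touchdown / stance-duration columns (deposit schema)."""
    path = Path(path)
    pd.DataFrame(
        {"touchdown": events.touchdown, "stance_duration": events.stance_duration}
    ).to_csv(path, index=False, float_format="%.17g")
    return path


def read_cycle_times_csv(path: str | Path) -> GaitCycleTimes:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("touchdown", "stance_duration"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return GaitCycleTimes(
        touchdown=df["touchdown"].to_numpy(),
        stance_duration=df["stance_duration"].to_numpy(),
    )


def write_sidecar(data: dict, path: str | Path) -> Path:
    """Write a JSON metadata/truth sidecar next to a fixture CSV."""
    path = Path(path)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(data, indent=1, default=_default))
    return path


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# Optional deposit (RData) reading
# ---------------------------------------------------------------------------

def _require_pyreadr():
    try:
        import pyreadr  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "Reading the RData deposit requires the optional 'pyreadr' "
            "dependency (pip install synlab[deposit])."
        ) from exc
    return pyreadr


def read_metadata_dat(path: str | Path) -> dict[str, TrialMeta]:
    """Read the deposit's whitespace-separated participant metadata."""
    df = pd.read_csv(path, sep=r"\s+")
    out: dict[str, TrialMeta] = {}
    for _, row in df.iterrows():
        meta = TrialMeta(
            participant=str(row.get("Code")),
            sex=row.get("Sex"),
            locomotion=row.get("Locomotion"),
            environment=row.get("Environment"),
            speed=float(row.get("Speed")) if "Speed" in row else None,
            age=float(row.get("Age")) if "Age" in row else None,
            height=float(row.get("Height")) if "Height" in row else None,
            mass=float(row.get("Mass")) if "Mass" in row else None,
        )
        out[f"{meta.participant}_{meta.environment}{meta.locomotion}"] = meta
    return out


def read_deposit(
    directory: str | Path,
) -> list[tuple[RawEmgRecording, GaitCycleTimes, TrialMeta]]:  # pragma: no cover
    """Load raw EMG and cycle times from the public RData deposit.

    Expects ``RAW_EMG.RData`` and ``CYCLE_TIMES.RData`` in
    ``directory`` (plus optionally ``metadata.dat``). Trials with
    fewer than 30 cycles (some overground running trials have 21-29)
    are accepted as-is; cycles are never reordered.
    """
    pyreadr = _require_pyreadr()
    directory = Path(directory)
    raw_rd = pyreadr.read_r(str(directory / "RAW_EMG.RData"))
    cyc_rd = pyreadr.read_r(str(directory / "CYCLE_TIMES.RData"))
    raw_list = next(iter(raw_rd.values()))
    cyc_list = next(iter(cyc_rd.values()))

    metas: dict[str, TrialMeta] = {}
    meta_path = directory / "metadata.dat"
    if meta_path.exists():
        metas = read_metadata_dat(meta_path)

    def _items(obj) -> Iterable[tuple[str, pd.DataFrame]]:
        if isinstance(obj, dict):
            return obj.items()
        return ((getattr(v, "name", str(i)), v) for i, v in enumerate(obj))

    raws: dict[tuple, pd.DataFrame] = {}
    for key, df in _items(raw_list):
        info = parse_trial_key(key)
        raws[(info["participant"], info["environment"], info["locomotion"], info["trial"])] = df

    out = []
    for key, df in _items(cyc_list):
        info = parse_trial_key(key)
        tag = (info["participant"], info["environment"], info["locomotion"], info["trial"])
        if tag not in raws:
            raise ValueError(f"cycle-times trial {key!r} has no matching raw EMG")
        raw_df = raws[tag]
        cols = list(raw_df.columns)
        missing = [m for m in MUSCLES if m not in cols]
        if missing:
            raise ValueError(f"{key}: raw EMG missing muscles {missing}")
        t = raw_df[cols[0]].to_numpy() if cols[0] not in MUSCLES else None
        fs = 1.0 / np.mean(np.diff(t)) if t is not None else 2000.0
        meta_key = f"{info['participant']}_{info['environment']}{info['locomotion']}"
        meta = metas.get(
            meta_key,
            TrialMeta(
                participant=info["participant"],
                environment=info["environment"],
                locomotion=info["locomotion"],
            ),
        )
        raw = RawEmgRecording(
            samples=np.vstack([raw_df[m].to_numpy() for m in MUSCLES]), fs=fs, meta=meta
        )
        events = GaitCycleTimes(
            touchdown=df.iloc[:, 0].to_numpy(), stance_duration=df.iloc[:, 1].to_numpy()
        )
        out.append((raw, events, meta))
    if not out:
        warnings.warn("deposit contained no trials")
    return out
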