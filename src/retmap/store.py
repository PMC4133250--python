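"""Single-file sqlite result store.

Tables: ``config`` (YAML text), ``segments`` / ``synapses`` / ``neurons``
(snapshots keyed by simulated time), ``spikes`` (optional), ``metrics``,
``checkpoints`` (full dynamic state as a compressed npz blob) and
``rng_states`` (inside the checkpoint blob).  Simulations can be resumed
from the latest checkpoint and reproduce the uninterrupted trajectory.
"""

from __future__ import annotations

import io
import sqlite3

import numpy as np
import pandas as pd
import yaml

from .config import SimulationConfig, config_from_dict, config_to_dict

SCHEMA_VERSION = 1

_TABLES = {
    "segments": "time_s REAL, segment_id INTEGER, parent_id INTEGER, "
                "rgc_id INTEGER, x1 REAL, y1 REAL, x2 REAL, y2 REAL, "
                "is_trunk INTEGER",
    "synapses": "time_s REAL, synapse_id INTEGER, rgc_id INTEGER, "
                "segment_id INTEGER, post_cell_id INTEGER, T REAL, "
                "created_ms INTEGER",
    "neurons": "time_s REAL, cell_id INTEGER, size REAL, h REAL, rate REAL",
    "spikes": "cell_id INTEGER, time_ms INTEGER",
    "metrics": "time_h REAL, name TEXT, value REAL",
    "checkpoints": "time_ms INTEGER, state BLOB",
}


class ResultStore:
    def __init__(self, path: str, record_spikes: bool = False):
        self.path = str(path)
        self.record_spikes = record_spikes
        self.conn = sqlite3.connect(self.path)
        cur = self.conn.cursor()
        cur.execute(
            "CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT)"
        )
        cur.execute(
            "INSERT OR REPLACE INTO meta VALUES ('schema_version', ?)",
            (str(SCHEMA_VERSION),),
        )
        cur.execute("CREATE TABLE IF NOT EXISTS config (yaml TEXT)")
        for name, cols in _TABLES.items():
            cur.execute(f"CREATE TABLE IF NOT EXISTS {name} ({cols})")
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- config -------------------------------------------------------------
    def save_config(self, cfg: SimulationConfig) -> None:
        text = yaml.safe_dump(config_to_dict(cfg), sort_keys=False)
        self.conn.execute("DELETE FROM config")
        self.conn.execute("INSERT INTO config VALUES (?)", (text,))
        self.conn.commit()

    def load_config(self) -> SimulationConfig:
        row = self.conn.execute("SELECT yaml FROM config").fetchone()
        if row is None:
            raise ValueError("store has no config")
        return config_from_dict(yaml.safe_load(row[0]))

    # -- snapshots ----------------------------------------------------------
    def save_tables(self, sim) -> None:
        t_s = sim.t_ms / 1000.0
        seg = sim.arbors.to_table()
        seg.insert(0, "time_s", t_s)
        seg = seg.drop(columns=["is_trunk"]).assign(
            is_trunk=sim.arbors.to_table()["is_trunk"].astype(int).values
        )
        seg.to_sql("segments", self.conn, if_exists="append", index=False)
        syn = sim.synapses.to_table()
        syn.insert(0, "time_s", t_s)
        syn.to_sql("synapses", self.conn, if_exists="append", index=False)
        neu = pd.DataFrame(
            {
                "time_s": t_s,
                "cell_id": np.arange(sim.neurons.n),
                "size": sim.neurons.size,
                "h": sim.neurons.h,
                "rate": sim.neurons.rate,
            }
        )
        neu.to_sql("neurons", self.conn, if_exists="append", index=False)
        self.conn.commit()

    def append_metrics(self, snap: dict) -> None:
        rows = [(snap["t_h"], k, float(v)) for k, v in snap.items() if k != "t_h"]
        self.conn.executemany("INSERT INTO metrics VALUES (?, ?, ?)", rows)
        self.conn.commit()

    def append_spikes(self, cells, times_ms) -> None:
        self.conn.executemany(
            "INSERT INTO spikes VALUES (?, ?)",
            zip(map(int, cells), map(int, times_ms)),
        )

    def read_table(self, name: str) -> pd.DataFrame:
        if name not in _TABLES and name != "config":
            raise KeyError(f"no such table {name!r}")
        return pd.read_sql(f"SELECT * FROM {name}", self.conn)

    # -- checkpoints ---------------------------------------------------------
    def save_checkpoint(self, sim) -> None:
        buf = io.BytesIO()
        np.savez_compressed(buf, **sim.state_dict())
        self.conn.execute(
            "INSERT INTO checkpoints VALUES (?, ?)",
            (int(sim.t_ms), buf.getvalue()),
        )
        self.conn.commit()

    def load_checkpoint(self, time_ms: int | None = None) -> dict:
        if time_ms is None:
            row = self.conn.execute(
                "SELECT state FROM checkpoints ORDER BY time_ms DESC LIMIT 1"
            ).fetchone()
        else:
            row = self.conn.execute(
                "SELECT state FROM checkpoints WHERE time_ms = ?", (int(time_ms),)
            ).fetchone()
        if row is None:
            raise ValueError("store has no matching checkpoint")
        try:
            with np.load(io.BytesIO(row[0])) as z:
                return {k: z[k] for k in z.files}
        except Exception as exc:  # corrupt blob
            raise ValueError(f"corrupt checkpoint: {exc}") from exc

    # -- export -------------------------------------------------------------
    def export_tables(self, outdir: str, names=("segments", "synapses", "neurons",
                                                "metrics", "spikes")) -> list[str]:
        """Write tables as CSV with deterministic column order; coordinates
        are µm, times in the column names' units (s, ms, h)."""
        import os

        paths = []
        for name in names:
            df = self.read_table(name)
            path = os.path.join(outdir, f"{name}.csv")
            df.to_csv(path, index=False)
            paths.append(path)
        return paths
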