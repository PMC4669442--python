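import numpy as np
import pandas as pd
import pytest

from secretracer.secretome import SpectralCountMatrix
from secretracer.tracer import ReporterPlateSet


def make_counts(counts: dict[str, list[int]], lengths: list[int],
                conditions: dict[str, str] | None = None) -> SpectralCountMatrix:
    """Build a SpectralCountMatrix from column dict {sample: counts}."""
    df = pd.DataFrame(counts)
    df.index = pd.Index([f"P{i:03d}" for i in range(len(df))], name="protein_id")
    if conditions is None:
        conditions = {s: s.rsplit("_", 1)[0] for s in df.columns}
    return SpectralCountMatrix(
        counts=df,
        lengths=pd.Series(lengths, index=df.index, name="length"),
        conditions=conditions,
    )


def make_plates(rows: list[tuple]) -> ReporterPlateSet:
    """Rows of (plate, well, reporter, condition, time_h, replicate, flux)."""
    df = pd.DataFrame(
        rows, columns=["plate", "well", "reporter", "condition", "time_h", "replicate", "flux"]
    )
    return ReporterPlateSet(data=df)


@pytest.fixture
def simple_plate() -> ReporterPlateSet:
    """One plate, one timepoint, 2 reporters, 3 replicates, TA and
    background wells; treated reporter G1 is 4x its control level."""
    rows = []
    w = iter(range(1000))
    for b in range(1, 5):
        rows.append(("p1", f"W{next(w)}", "none", "background", 0.0, b, 100.0))
    for cond in ("treated", "control"):
        for r in range(1, 4):
            rows.append(("p1", f"W{next(w)}", "TA", cond, 0.0, r, 10000.0))
            g1 = 40000.0 if cond == "treated" else 10000.0
            rows.append(("p1", f"W{next(w)}", "G1", cond, 0.0, r, g1))
            rows.append(("p1", f"W{next(w)}", "G2", cond, 0.0, r, 20000.0))
    return make_plates(rows)


@pytest.fixture
def moderated_fixture() -> pd.DataFrame:
    """Fixed 6-reporter, 3-timepoint, 3-replicate activity table with
    heterogeneous per-reporter noise, frozen by seed."""
    rng = np.random.default_rng(42)
    rows = []
    for g in range(6):
        for t in (0.0, 2.0, 4.0):
            mu = rng.normal(0.0, 1.0)
            for r in range(1, 4):
                rows.append((f"G{g}", t, r, mu + rng.normal(0.0, 0.3 * (g + 1) / 3)))
    return pd.DataFrame(rows, columns=["reporter", "time_h", "replicate", "y"])
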