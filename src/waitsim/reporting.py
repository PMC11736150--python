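"""Heatmap-table rendering of grid results.

One wide-format CSV per outcome per panel (rows = medium-risk size, columns
= high-risk size, cells = "value (RR)") plus a low-risk wait table per
panel. Rounding is applied at display time only; the raw full-precision
table is always written alongside. Every file opens with a comment line
carrying the seed and config hash so outputs are traceable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DomainError, MissingInputError
from .grid import GridResult

OUTCOME_COLUMNS = {
    "mortality": ("mortality_pct", "rr_mortality"),
    "hospitalization": ("hospitalization_pct", "rr_hospitalization"),
    "urgent": ("urgent_pct", "rr_urgent"),
}


@dataclass
class ReportConfig:
    output_dir: Path
    percent_decimals: int = 1
    rr_decimals: int = 2
    weeks_decimals: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)


def _meta_line(config: ReportConfig) -> str:
    if not config.metadata:
        return "# waitsim report\n"
    parts = ", ".join(f"{k}={v}" for k, v in sorted(config.metadata.items()))
    return f"# {parts}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: ReportConfig, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_line(config))
        df.to_csv(fh, index=index)


def write_heatmap_tables(result: GridResult, config: ReportConfig) -> list[Path]:
    """Render one CSV per outcome per three-group panel, plus wait tables.

    Returns the list of files written. The raw per-row table goes to
    ``grid_results.csv`` with full precision.
    """
    if result.table.empty:
        raise DomainError("grid result is empty; nothing to report")
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    raw_path = out / "grid_results.csv"
    _write_csv(result.table, raw_path, config, index=False)
    written.append(raw_path)

    three = result.table[result.table["kind"].isin(["three_group", "equal_thirds"])]
    panels = sorted(
        {(int(hw), int(mi)) for hw, mi in zip(three["high_wait"], three["medium_increment"])}
    )
    pdp, rdp, wdp = config.percent_decimals, config.rr_decimals, config.weeks_decimals
    for hw, mi in panels:
        panel = three[
            (three["high_wait"] == hw)
            & (three["medium_increment"] == mi)
            & (three["kind"] == "three_group")
        ]
        if panel.empty:
            continue
        for outcome, (val_col, rr_col) in OUTCOME_COLUMNS.items():
            cells = panel.assign(
                cell=[
                    f"{v:.{pdp}f} ({r:.{rdp}f})" if pd.notna(v) else "infeasible"
                    for v, r in zip(panel[val_col], panel[rr_col])
                ]
            )
            wide = cells.pivot(index="medium_size", columns="high_size", values="cell")
            path = out / f"heatmap_{outcome}_hw{hw}_mi{mi}.csv"
            _write_csv(wide, path, config, index=True)
            written.append(path)
        waits = panel.assign(
            cell=[
                f"{w:.{wdp}f}" if pd.notna(w) else "infeasible"
                for w in panel["solved_low_wait"]
            ]
        ).pivot(index="medium_size", columns="high_size", values="cell")
        path = out / f"low_wait_hw{hw}_mi{mi}.csv"
        _write_csv(waits, path, config, index=True)
        written.append(path)
    return written


_CELL_RE = re.compile(r"^\s*([0-9.]+)\s*\(([0-9.]+)\)\s*$")


def parse_heatmap_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a written heatmap CSV back into (value, RR) frames.

    Round-trip helper: recovers the displayed numbers (at display rounding)
    from the "value (RR)" cells.
    """
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"expected heatmap table at {path}")
    wide = pd.read_csv(path, comment="#", index_col=0)
    values = wide.copy()
    rrs = wide.copy()
    for col in wide.columns:
        parsed = [_CELL_RE.match(str(c)) for c in wide[col]]
        values[col] = [float(m.group(1)) if m else float("nan") for m in parsed]
        rrs[col] = [float(m.group(2)) if m else float("nan") for m in parsed]
    return values, rrs
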