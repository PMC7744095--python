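#!/usr/bin/env python
"""Best-effort converter for the published Figure 3 source-data files.

The journal distributes the summary-plot and histogram source data as
spreadsheet/CSV files whose exact layout is not standardized.  This
script sniffs the input and writes the two tables the test suite's
replication check consumes:

  data/figure3_source/rates.csv         (condition, replicate, n_events, t_observable_s)
  data/figure3_source/fret_samples.csv  (condition, window, efficiency)

Usage:
  python contrib/convert_figure3_source_data.py SOURCE_FILE [SOURCE_FILE ...] \
      --out data/figure3_source/

Column matching is heuristic (case-insensitive substring search for
event/count, time/possible/denominator, rate, FRET/efficiency,
condition/sample, replicate/movie); inspect the output before trusting
it.  If a file only provides per-replicate *rates* (no counts and
times), pseudo-counts are written so that pooled rates reproduce the
replicate mean; the Poisson interval is then meaningless and only the
replicate-based statistics should be used.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import pandas as pd

CONDITION_ALIASES = {
    "wt": ("wt", "wild", "xlf wt", "delta xlf + wt"),
    "buffer": ("buffer", "no xlf", "mock"),
    "tail_truncated": ("245", "truncat", "1-245"),
}


def _find(columns, *needles):
    for c in columns:
        lc = str(c).lower()
        if any(n in lc for n in needles):
            return c
    return None


def _canonical_condition(raw: str) -> str:
    lc = str(raw).lower()
    for canon, needles in CONDITION_ALIASES.items():
        if any(n in lc for n in needles):
            return canon
    return str(raw)


def _load_tables(path: Path) -> dict[str, pd.DataFrame]:
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=None)
    return {path.stem: pd.read_csv(path)}


def convert(paths: list[Path], out_dir: Path) -> None:
    rate_rows, sample_rows = [], []
    for path in paths:
        for sheet, df in _load_tables(path).items():
            cols = list(df.columns)
            c_cond = _find(cols, "condition", "sample", "protein")
            c_rep = _find(cols, "replicate", "movie", "rep")
            c_events = _find(cols, "event", "count", "n_sr")
            c_time = _find(cols, "possible", "observable", "total time", "denominator")
            c_rate = _find(cols, "rate")
            c_fret = _find(cols, "fret", "efficiency")
            c_window = _find(cols, "window", "interval", "fov", "min")

            if c_fret is not None:
                for _, row in df.iterrows():
                    sample_rows.append(
                        {
                            "condition": _canonical_condition(
                                row[c_cond] if c_cond else sheet
                            ),
                            "window": row[c_window] if c_window else "pooled",
                            "efficiency": row[c_fret],
                        }
                    )
            elif c_events is not None and c_time is not None:
                for i, row in df.iterrows():
                    rate_rows.append(
                        {
                            "condition": _canonical_condition(
                                row[c_cond] if c_cond else sheet
                            ),
                            "replicate": row[c_rep] if c_rep else i,
                            "n_events": int(row[c_events]),
                            "t_observable_s": float(row[c_time]),
                        }
                    )
            elif c_rate is not None:
                # rates only: synthesize counts over a nominal time base
                for i, row in df.iterrows():
                    t_nominal = 1e6
                    rate_rows.append(
                        {
                            "condition": _canonical_condition(
                                row[c_cond] if c_cond else sheet
                            ),
                            "replicate": row[c_rep] if c_rep else i,
                            "n_events": int(round(float(row[c_rate]) * t_nominal)),
                            "t_observable_s": t_nominal,
                        }
                    )
            else:
                print(f"  [skip] {path.name}:{sheet}: no recognizable columns", file=sys.stderr)

    out_dir.mkdir(parents=True, exist_ok=True)
    if rate_rows:
        pd.DataFrame(rate_rows).to_csv(out_dir / "rates.csv", index=False)
        print(f"wrote {out_dir / 'rates.csv'} ({len(rate_rows)} rows)")
    if sample_rows:
        pd.DataFrame(sample_rows).to_csv(out_dir / "fret_samples.csv", index=False)
        print(f"wrote {out_dir / 'fret_samples.csv'} ({len(sample_rows)} rows)")
    if not rate_rows and not sample_rows:
        sys.exit("no convertible tables found")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("sources", nargs="+", type=Path)
    ap.add_argument("--out", type=Path, default=Path("data/figure3_source"))
    args = ap.parse_args()
    convert(args.sources, args.out)
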