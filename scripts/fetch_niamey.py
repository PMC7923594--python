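"""Fetch the Niamey 2016 probability-of-precipitation worked-example data.

Downloads the forecast/realization table deposited in the public
replication repository (github.com/TimoDimi/replication_DGJ20) and
writes it to data/precip_Niamey_2016.csv with columns

    obs, ENS, EPC, EMOS, Logistic

(92 rows: daily 24-h-ahead forecasts at Niamey, Niger, July-September
2016).  Requires network access; everything else in this package runs
on synthetic data, and the tests that use this file skip when it is
absent.

Usage:
    python scripts/fetch_niamey.py            # download
    python scripts/fetch_niamey.py --from X   # convert a local copy
"""

import argparse
import io
import sys
import tarfile
import urllib.request
from pathlib import Path

import pandas as pd

REPO_TARBALL = (
    "https://github.com/TimoDimi/replication_DGJ20/archive/refs/heads/master.tar.gz"
)
TARGET = Path(__file__).resolve().parents[1] / "data" / "precip_Niamey_2016.csv"
COLUMNS = ["ENS", "EPC", "EMOS", "Logistic"]


def _normalise(df: pd.DataFrame) -> pd.DataFrame:
    rename = {}
    for col in df.columns:
        low = col.strip().lower()
        if low in ("obs", "observation", "y", "rain", "precip_event"):
            rename[col] = "obs"
        for want in COLUMNS:
            if low == want.lower():
                rename[col] = want
    df = df.rename(columns=rename)
    missing = [c for c in ["obs"] + COLUMNS if c not in df.columns]
    if missing:
        raise SystemExit(
            f"could not identify columns {missing} in {sorted(df.columns)}; "
            "pass a prepared CSV via --from"
        )
    return df[["obs"] + COLUMNS]


def _candidate_tables(payload: bytes):
    with tarfile.open(fileobj=io.BytesIO(payload), mode="r:gz") as tar:
        for member in tar.getmembers():
            if member.name.lower().endswith((".csv", ".txt")):
                fh = tar.extractfile(member)
                if fh is None:
                    continue
                try:
                    yield member.name, pd.read_csv(fh)
                except Exception:
                    continue


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--from", dest="local", type=Path, default=None,
                        help="Use a local CSV instead of downloading.")
    args = parser.parse_args(argv)

    if args.local is not None:
        df = _normalise(pd.read_csv(args.local))
    else:
        print(f"downloading {REPO_TARBALL} ...")
        payload = urllib.request.urlopen(REPO_TARBALL, timeout=60).read()
        df = None
        for name, table in _candidate_tables(payload):
            try:
                df = _normalise(table)
            except SystemExit:
                continue
            print(f"found forecast table in {name}")
            break
        if df is None:
            raise SystemExit(
                "no table with obs/ENS/EPC/EMOS/Logistic columns found in the "
                "repository; download the data manually and rerun with --from"
            )
    TARGET.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(TARGET, index=False)
    print(f"wrote {len(df)} rows to {TARGET}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
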