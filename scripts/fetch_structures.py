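#!/usr/bin/env python
"""Download the receptor-ectodomain crystal structures used by the
acceptance targets into ``data/pdb/`` (plain-text PDB).

Requires network access to files.rcsb.org.  Run once; afterwards the test
suite and ``scripts/acceptance.py`` pick the files up automatically.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

PDB_IDS = ["1NQL", "3QWQ", "1YY9", "1IVO"]
OUT = Path(__file__).resolve().parent.parent / "data" / "pdb"


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    failures = 0
    for pdb_id in PDB_IDS:
        dest = OUT / f"{pdb_id.lower()}.pdb"
        if dest.exists():
            print(f"{pdb_id}: already present")
            continue
        url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
        try:
            with urllib.request.urlopen(url, timeout=60) as resp:
                dest.write_bytes(resp.read())
            print(f"{pdb_id}: fetched {dest.stat().st_size} bytes")
        except OSError as exc:
            print(f"{pdb_id}: FAILED ({exc})", file=sys.stderr)
            failures += 1
    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
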