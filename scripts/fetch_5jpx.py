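#!/usr/bin/env python
"""Download the deposited B-box2 ensemble (PDB 5JPX) and its restraint file
into data/, where the deposit-dependent acceptance tests expect them.

Requires network access to files.rcsb.org.
"""

import urllib.request
from pathlib import Path

URLS = {
    "5JPX.pdb": "https://files.rcsb.org/download/5JPX.pdb",
    "5JPX.mr": "https://files.rcsb.org/download/5JPX.mr",
}


def main():
    data = Path(__file__).resolve().parent.parent / "data"
    data.mkdir(exist_ok=True)
    for name, url in URLS.items():
        target = data / name
        if target.exists():
            print(f"{target} already present")
            continue
        print(f"fetching {url} ...")
        with urllib.request.urlopen(url, timeout=30) as resp:
            target.write_bytes(resp.read())
        print(f"wrote {target} ({target.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
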