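#!/usr/bin/env python
"""Regenerate the checked-in JSON copy of the core model from code.

Run from the repository root after changing the fixture builder:

    python scripts/regenerate_core_model.py
"""

from pathlib import Path

from glycferm.fixtures import build_core_model
from glycferm.io import write_model


def main() -> None:
    target = Path(__file__).resolve().parents[1] / "src" / "glycferm" / "data" / "core_model.json"
    model = build_core_model()
    write_model(model, target, "json")
    print(f"wrote {target} ({len(model.reactions)} reactions, "
          f"{len(model.metabolites)} metabolites)")


if __name__ == "__main__":
    main()
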