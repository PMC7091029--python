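"""Regenerate the golden pipeline outputs used by the determinism tests.

Run from the repository root after any intentional change to the pipeline's
reports: ``python scripts/make_golden.py``
"""

from pathlib import Path
import shutil
import sys
import tempfile

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "tests"))

from latedating import pipeline as pl  # noqa: E402
from test_pipeline import GOLDEN_DIR, fixture_run_config  # noqa: E402


def main() -> None:
    GOLDEN_DIR.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory() as tmp:
        paths = pl.write_reports(pl.run_pipeline(fixture_run_config()), tmp)
        for name in ("agreement.tsv", "flow_summary.tsv"):
            shutil.copy(paths[name], GOLDEN_DIR / name)
            print(f"wrote {GOLDEN_DIR / name}")


if __name__ == "__main__":
    main()
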