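#!/usr/bin/env python
"""Protection-coverage overlay on the priority and loss-significant areas.

Overlays the per-cell percent-protected field on each score's hotspot
set and reports, per score, the overall percent of the hotspot surface
under protection, the number of hotspot cells with no protection at all,
and the number with at least half their surface protected.

Writes hotspot_protection_classes.csv and protection_summary.json under
results/spatial/ (next to the hotspot masks it consumes).
"""

from pathlib import Path

from expdiv import pipeline

IN = Path("results/synthetic_inputs")
OUT = Path("results/spatial")


def main() -> None:
    cfg = pipeline.RunConfig(
        coverage=str(IN / "coverage.csv"),
        out=str(OUT),
        seed=20260401,
    )
    res = pipeline.run_protection_analysis(cfg)
    for name in ("GexpPD", "LexpPD", "TOP_HEDGE", "TOP_LEDGE"):
        s = res["summaries"][name]
        print(
            f"{name:10s} hotspots: {s.overall_percent:5.1f}% protected overall; "
            f"{s.n_not_protected} cells unprotected, "
            f"{s.n_heavily_protected} cells >= {s.heavy_threshold:.0f}% protected "
            f"(of {s.n_cells})"
        )
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
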