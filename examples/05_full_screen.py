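"""Run the full screen end to end on synthetic data.

Executes signature -> orthogonality ranking -> network assessment -> synergy
scoring with one seeded configuration, and prints the assembled report.  The
same pipeline runs from the shell as `combiscreen screen --config cfg.yaml`.
"""

import json

from combiscreen.pipeline import run_screen

report = run_screen(config={"seed": 42, "output_dir": "screen_out"})

print("top-ranked partner candidates:", report.ranking["top"])
for entry in report.exposure:
    if entry["status"] == "ok":
        print(
            f"pair {entry['pair']}: z_A={entry['z_a']:+.2f} z_B={entry['z_b']:+.2f} "
            f"s_AB={entry['s_ab']:+.2f} -> {entry['category']}"
        )
    else:
        print(f"pair {entry['pair']}: {entry['status']} ({entry['reason']})")
for entry in report.synergy:
    print(
        f"pair {entry['pair']}: Bliss {entry['bliss']['synergy_score']:+.2f} pp, "
        f"ZIP {entry['zip']['synergy_score']:+.2f} pp "
        f"(planted {entry['planted_delta_pp']:+.0f} pp)"
    )
print("full report and stage TSVs written to screen_out/")
print(json.dumps(report.stages, indent=2))
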