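"""Metrics over a round log loaded back from CSV.

Round logs are plain CSV (one row per round) plus a JSON config sidecar,
so any analysis can be replayed from disk — including logs produced
elsewhere, as long as they follow the same schema.
"""
import tempfile
from pathlib import Path

from crl_exes import (
    logs_from_frame,
    make_condition,
    play_dyad,
    read_log_csv,
    write_log_csv,
)
from crl_exes.metrics import summarize_condition

out = Path(tempfile.mkdtemp()) / "rounds.csv"
logs = [play_dyad(make_condition("ballistic", "low"), seed, dyad_id=i)
        for i, seed in enumerate((3, 4, 5))]
write_log_csv(logs, out, config={"note": "three demo dyads"})
print(f"wrote {out} ({out.stat().st_size} bytes) + config sidecar")

back = logs_from_frame(read_log_csv(out))
rep = summarize_condition(back)
for metric, agg in rep.summary.items():
    print(f"{metric:18s} mean {agg['mean']:.3f}  sem {agg['sem']:.3f}  n={agg['n']}")
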