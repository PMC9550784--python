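"""Run the full pipeline under both conditions and call cascade activation.

Shows the Bayesian 2-of-3 STR-similarity verdicts for every cascade edge and
candidate edge, the negative-control noise floor, and the resulting
activation calls: without stress only the proliferative SRME cascade is
active; under starvation stress the AMMJ cascade activates as well.
"""

from sigstr import PipelineConfig, run_pipeline

for stressed in (False, True):
    cfg = PipelineConfig(simulate_stressed=stressed, seed=42)
    report = run_pipeline(cfg)
    label = "stressed" if stressed else "non-stressed"
    print(f"\n=== {label} ===")
    print(f"noise floor: {report['noise_floor']['value']:.2e} /min "
          f"({report['noise_floor']['source']})")
    print(f"{'pair':<14} {'|d mu|':>7} {'|delta|':>8} {'pi_d':>6} "
          f"{'d_pi':>6}  verdict")
    for s in report["similarity"]:
        pair = "-".join(s["pair"])
        verdict = "similar" if s["similar"] else "different"
        print(f"{pair:<14} {s['d_mu']:>7.4f} {s['effect_size']:>8.2f} "
              f"{s['pi_d']:>6.2f} {s['d_pi']:>6.2f}  {verdict}")
    for call in report["cascades"]:
        state = "ACTIVATED" if call["activated"] else "not activated"
        detail = ""
        if call["failing_edges"]:
            detail += f" failing edges: {call['failing_edges']}"
        if call["below_floor"]:
            detail += f" below floor: {call['below_floor']}"
        print(f"cascade {call['name']}: {state}{detail}")
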