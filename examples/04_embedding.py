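"""Embed per-molecule replicate STR vectors in 2-D with t-SNE.

Each molecule is represented by its replicate STR values with the minimum
and maximum removed (6 replicates -> 4-dimensional vectors). Under stress
the AMMJ-cascade molecules separate from the SRME-cascade molecules; the
mean silhouette coefficient quantifies the separation.
"""

from sigstr import PipelineConfig, run_pipeline

for stressed in (False, True):
    report = run_pipeline(PipelineConfig(simulate_stressed=stressed, seed=42))
    label = "stressed" if stressed else "non-stressed"
    print(f"\n=== {label} ===")
    srme = {"Src", "Raf1", "MEK1", "ERK1"}
    ammj = {"ASK1", "MKK4", "MKK3", "JNK"}
    for mol, (x, y) in sorted(report["embedding"].items()):
        tag = "SRME" if mol in srme else "AMMJ" if mol in ammj else ""
        print(f"  {mol:<8} ({x:>8.2f}, {y:>8.2f}) {tag}")
    print(f"SRME/AMMJ cluster separation (mean silhouette): "
          f"{report['cluster_separation']:.3f}")
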