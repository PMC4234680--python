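"""Simulate one SDB-like and one healthy overnight recording and extract
the windowed SpO2 + pulse-rate-variability features.

Run:  python examples/simulate_and_extract.py
"""

import numpy as np

import oxiscreen as ox

cfg = ox.PipelineConfig(min_windows=10)

for name, group in [("SDB-like", ox.SDB_DEFAULTS), ("NonSDB-like", ox.NONSDB_DEFAULTS)]:
    rec, truth = ox.simulate_recording(group.replace(duration_s=1800.0), seed=7,
                                       subject_id=name)
    table = ox.extract_window_features(rec, cfg)
    vec = ox.extract_features(rec, cfg)
    print(f"\n{name}: {rec.duration_s/60:.0f} min, {len(truth['event_times'])} planted "
          f"desaturation events, {len(table)} analysis windows")
    print(f"  modulation-band power ratio  M_R      = {vec.features['M_R']:.3f}")
    print(f"  spectral Shannon entropy     M_SE     = {vec.features['M_SE']:.2f} bits")
    print(f"  delta index                  M_Delta  = {vec.features['M_Delta']:.3f} %")
    print(f"  desaturations per window     M_n2     = {vec.features['M_n2']:.2f}")
    print(f"  normalized LF power (PRV)    M_LF     = {vec.features['M_LF']:.3f}")
    print(f"  mean pulse interval          M_RR     = {vec.features['M_RR']:.3f} s")

print("""
Reading the numbers: the SDB-like recording concentrates SpO2 spectral
power in the 0.005-0.1 Hz modulation band (higher M_R, lower M_SE), is
more variable (M_Delta, M_n2), and shows the sympathetic signature of
recurring events in the pulse rate (higher M_LF, shorter M_RR).""")
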