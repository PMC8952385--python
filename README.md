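# mzjoint

Joint LC-MS feature extraction for untargeted metabolomics / exposomics.

`mzjoint` combines three complementary extraction tiers on centroided DDA
LC-MS/MS runs:

1. **PP** — centWave-style chromatographic peak picking (ROI detection +
   continuous-wavelet peak localisation) on MS1 scans.
2. **MR** — rescue of features missed by peak picking via their DDA MS2
   precursors: precursor deduplication, novelty check against PP, automatic
   relocation to the chromatographic peak apex, and validation against the
   local noise level (3-fold by default) and a >= 4-consecutive-MS1-scan
   requirement.
3. **TL** — direct targeted extraction of user-listed compounds (m/z + RT)
   that neither PP nor MR recovered, with the same noise validation and a
   guard against duplicating freshly rescued MR features.

Downstream, the package provides cross-sample feature grouping with gap
filling, MS2 spectral-library annotation by weighted dot product, and
calibration-curve LOD estimation (intensity at 3x S/N fitted into an OLS
regression), including PP-only vs joint-tier LOD comparison.

A seeded synthetic DDA generator (`mzjoint.simulate`) produces mzML runs
with exact ground truth — Gaussian, fronting/tailing (EMG), shoulder and
spike peak shapes over a matrix baseline, with top-N MS2 triggering and
dynamic exclusion — so the whole pipeline is testable without instrument
data.

## Quick start

```sh
# generate a synthetic DDA run
mzjoint simulate --seed 1 --out run.mzml --truth-out truth.csv

# peak picking, MS2 rescue, targeted extraction
mzjoint pick run.mzml --out pp.csv
mzjoint rescue run.mzml --picked pp.csv --out mr.csv
mzjoint target run.mzml --targets targets.csv --existing pp.csv --out tl.csv

# full workflow from a YAML config
mzjoint run --config workflow.yaml
```

A workflow config nests per-module sections:

```yaml
mode: full            # full | pp_only | tl_only | external_table_in
sample_paths: [a.mzml, b.mzml]
target_list_path: targets.csv   # optional (required for tl_only)
library_path: library.msp       # optional, enables annotation
output_dir: out
pp:  {ppm_tol: 10, peakwidth_min: 5, peakwidth_max: 20, sn_threshold: 3}
mr:  {dedup_mz_tol: 0.01, dedup_rt_tol: 30, confirm_mass_tol: 0.01,
      confirm_rt_tol: 60, noise_fold: 3, min_consecutive_scans: 4}
tl:  {mass_tol: 0.01, rt_tol: 30}
alignment: {bw: 5, mzwid: 0.015, minfrac: 0.5, minsamp: 1}
```

Python API mirrors the CLI:

```python
from mzjoint import (read_mzml, PeakPickingConfig, pick_peaks,
                     MRConfig, run_mr, TLConfig, run_tl)

run = read_mzml("sample.mzml")
pp = pick_peaks(run, PeakPickingConfig())
mr = run_mr(run, pp, MRConfig())
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (rescue gain,
dilution trends, tier disjointness, apex-relocation accuracy, LOD
direction, oracle equivalences, determinism), all evaluated on seeded
synthetic data.

## File formats

- **mzML** (read; written by the synthetic generator): centroided spectra,
  64-bit uncompressed arrays on write; zlib/32-bit accepted on read;
  RTs normalised to seconds. Profile-mode spectra are rejected.
- **MSP** (read): `Name:` / `PRECURSORMZ:` / `Num Peaks:` records; entries
  without precursor m/z or peaks are skipped.
- **Feature table CSV** (read/write):
  `feature_id,mz,rt,rtmin,rtmax,intensity,area,source,ms2_scan`.
- **Targeted list CSV** (read): `name,mz,rt` (RT in seconds).
- **Aligned table CSV** (write):
  `group_id,mz_med,rt_med,source_summary,<sample...>,filled_flags`.
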