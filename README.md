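# divesearch

Behavioral annotation of central-place-forager GPS tracks, and validation of
the inferred *search* behavior against prey-capture events from time–depth
recorders (TDRs).

Movement ecologists routinely label seabird GPS fixes as *search*, *travel*
or *rest* and treat search as a proxy for foraging. Whether search actually
coincides with prey capture is testable when birds also carry a depth logger:
every excursion below 1 m is a plunge dive, time-stamped and matchable to a
GPS fix. `divesearch` implements the full comparison pipeline for this kind
of study:

- **Preprocessing** — UTM projection, linear interpolation to a 2-min fix
  interval, per-fix metrics (step length, speed, acceleration, turning angle,
  9-fix tortuosity), removal of fixes within 5 km of the colony or between
  civil sunset and sunrise, trip splitting at colony visits.
- **Five point-wise annotators**, each a scikit-learn-style estimator
  (`fit` / `predict` over a trajectory frame):
  - `FPTAnnotator` — first passage time: FPT(r) is the time to cross a circle
    of radius *r* centered on each 500-m path point; *r\** maximizes
    S(r) = var(ln FPT) per bird; the highest-FPT sextile of points seeds a
    union-of-circles search area.
  - `KMeansAnnotator` — MacQueen online k-means on z-scored
    (step length, |turn|), cluster count by the elbow rule on explained
    variance.
  - `ThresholdAnnotator` — expert speed–tortuosity rules
    (search if tortuosity < 0.9 ∧ speed > 1 m/s, or 1.5 < speed < 9 m/s, or
    tortuosity ≥ 0.9 ∧ acceleration < −4 m/s²).
  - `HMMAnnotator` — 3-state hidden Markov model with gamma step lengths and
    von Mises turning angles, fitted by direct maximization of the scaled
    forward likelihood; Viterbi decoding.
  - `EMbCAnnotator` — expectation–maximization binary clustering of
    (speed, |turn|) into low/high quadrant bins.
- **Kernel density + spatial correlation** — quartic-kernel intensity
  surfaces of fixes and dives on a 10-km grid, compared with the
  Dutilleul/Clifford–Richardson modified t-test
  (F = r²(M̂ − 2)/(1 − r²) on F(1, M̂ − 2), with the effective sample size M̂
  shrunk by the product of the two correlograms).
- **Dive prediction** — gradient-boosted trees on
  (step, speed, |turn|, solar hour, tortuosity), 75/25 stratified split,
  bootstrap-tuned, Youden-J operating point; evaluated by confusion matrix,
  Cohen's κ and dive recall, including cross-colony transfer.
- **Search-chain evaluation** — a chain is a maximal run of consecutive
  search fixes within a trip. Per method: % dives inside search (true
  positives), % chains with no dive (false positives), % dives outside
  search (false negatives), % fixes searching, mean chain length, and
  Kendall's τ-b between chain length and dives per chain.
- **Synthetic data** — a seeded central-place trip simulator with a latent
  3-state Markov chain, state-specific gamma/von Mises emissions, colony
  commute bias and state-dependent dive probabilities, providing ground
  truth the real study obtains from TDRs.

## Worked example

```python
import divesearch as ds
from divesearch.reference import make_reference_dataset

data = make_reference_dataset(seed=0)          # two simulated colonies
report = ds.compare_methods(
    data, ds.default_annotators(random_state=0),
    ml_params={"n_resamples": 30, "random_state": 0},
)
cols = ["method", "colony", "tp_rate", "fp_rate", "pct_searching", "mean_chain_len"]
print(report[cols].head(6).round(1).to_string(index=False))
```

prints (for the `saltee` colony):

```
    method colony  tp_rate  fp_rate  pct_searching  mean_chain_len
       fpt saltee     86.5     21.6           60.7            28.8
    kmeans saltee     80.3     65.6           50.7             3.6
thresholds saltee     93.3     47.4           53.3             6.0
       hmm saltee     91.0     34.1           45.1             9.7
      embc saltee     48.9     76.1           36.4             2.1
     truth saltee     99.4     27.5           45.4            10.0
```

Reading: 91% of matched dives fall on HMM-labeled search fixes while 34% of
HMM search chains contain no dive; the ground-truth labels (available only
because the data are simulated) bound what any annotator could achieve. FPT
produces the longest chains; EMbC the shortest and the weakest dive capture —
the same qualitative ordering reported in gannet field studies.

A command-line interface mirrors the library:

```bash
divesearch simulate --n-birds 6 --seed 0 --out data/
divesearch annotate --tracks data/tracks.csv --dives data/dives.csv \
    --method hmm --colony -6.62189 52.11286 --out annotated.csv
divesearch compare --tracks data/tracks.csv --dives data/dives.csv \
    --colony -6.62189 52.11286 --out report.csv
```

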