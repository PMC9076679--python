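# ctcrw — covariate-driven continuous-time correlated random walks for whale telemetry

`ctcrw` is a Python library for asking how the movement of satellite-tagged
marine mammals responds to their environment. It was built around the
migration of Southwest Atlantic humpback whales (*Megaptera novaeangliae*)
from Brazilian breeding grounds to Southern Ocean feeding grounds, but the
machinery is generic: irregular, error-prone Argos fixes in; interpretable
movement parameters, model comparisons, behavioural classification and
habitat maps out.

## The model

The true velocity of an animal follows an Ornstein–Uhlenbeck process and
position integrates velocity (the continuous-time correlated random walk,
CTCRW):

    dv = −β v dt + σ dW,        dx = v dt

* **σ** (km h⁻³ᐟ²) sets the overall variability of velocity — big σ, fast
  travel; * **β** (h⁻¹) is the decay rate of velocity autocorrelation —
  big β, quickly-turning movement. Persistence is usually quoted as
  **p = 3/β** (hours). Slow, tortuous movement (low σ, low p) is the
  classical *area-restricted search* (ARS) signature of foraging.

Both parameters vary along the track through log-linear links to
standardized environmental covariates X_t (SST, SST anomaly, chlorophyll,
wind-stress curl, depth, winter/spring sea-ice presence, distance to the
southern ACC boundary), with optional deviation terms for a binary group
G (mothers vs males+, or tagging period):

    log σ_t = (A0 + a0 G) + Σ_j (A_j + a_j G) X_jt
    log β_t = (B0 + b0 G) + Σ_j (B_j + b_j G) X_jt

Exact discretization over each inter-fix interval gives a linear-Gaussian
state space; the marginal likelihood is computed exactly by a Kalman
filter (numba-accelerated), observations entering through per-fix error
SDs decomposed from Argos error ellipses (or imputed from per-class gamma
regressions on latitude for older tags). Models are fitted per animal
(**I-models**) or pooled across the fleet (**P-models**), candidate
covariate sets are enumerated subject to a Pearson collinearity screen
and ranked by AIC, and the selected fit drives quartile/ARS
classification and 0.1°-style gridded predictions of expected σ and p.

## Worked example

`examples/02_fit_pooled_model.py` simulates 20 whales (150 fixes each)
whose movement responds to SST and August ice presence with sex-group
deviations, then refits the pooled model:

```
model SST+ICE08+SEX: logLik -11517.2, AIC 23058.3, k = 12
coefficient                    truth  estimate     SE
A0 (log sigma intercept)        0.00    -0.052  0.039
B0 (log beta intercept)        -1.50    -1.569  0.093
A_SST                           0.37     0.253  0.085
B_SST                          -0.40    -0.536  0.200
B_ICE08                         0.47     0.586  0.302
b_ICE08                         1.00     1.584  0.678
...
```

Every generating coefficient is recovered within a few standard errors.
`B_ICE08 > 0` with a large positive mothers' deviation `b_ICE08` means β
rises sharply — persistence collapses — where winter ice occurred: the
ARS/foraging response, strongest for mothers.

`examples/03_reference_tables.py` pushes the shipped 22-whale deployment
summary through the descriptive pathways:

```
migratory duration, all whales (n=21): mean 37.6 d, median 35 d, range 25-71 d
  mothers  mean 40.9 d, median 38 d
  males+   mean 33.9 d, median 30 d
fix counts: mean 1166.4, median 1049
tracking duration: median 82.0 d, sample SD 52.0 d
ice-effect ratios: sigma males+ 1.08, beta males+ 0.625, beta mothers 0.07
```

The ratio 0.07 says mothers' β was ~14× higher (persistence ~14× lower)
in previously ice-covered habitat than in ice-free habitat.

The other examples cover fleet simulation and censoring (`01`),
behavioural classification and gridded prediction (`04`), and the
end-to-end pipeline with provenance manifest (`05`). A thin CLI mirrors
the pipeline: `ctcrw simulate | ingest | errors | run ...`.

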