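# fallwatch

Probabilistic human-posture classification and staged fall alarms from
bounding-box centroid trajectories.

Contactless fall monitoring typically runs a person detector on a fixed
camera and must decide, from nothing but the stream of detected bounding
boxes, whether the person is moving normally, becoming unstable, or falling.
`fallwatch` implements the statistical half of such a system for people who
want to study or deploy it without GPUs or video data: it consumes
time-stamped bounding-box streams (CSV/JSON), learns an interpretable
probabilistic model of posture dynamics, and raises staged alarms —
Warning1 when the trajectory enters a transition region, Warning2 when it
enters the falling region — typically *before* the body comes to rest.

## The model

Each frame's box is reduced to its centroid in normalized image coordinates
plus backward-difference speeds, giving the instant feature
f(t) = (x, y, vx, vy).  A light self-attention block gates these features
over a sliding 21-frame window,

    c(t) = 4 · softmax(G f(t) + b),    o(t) = c(t) ⊙ f(t) + f(t),

pools o(t) over the window and projects to a 2-D sample s.  The samples are
modeled by a Gaussian mixture whose parameters are themselves latent:

    α ~ Dirichlet(D),   μ_k ~ N(N1_k, diag(N2_k²)),   Λ_k ~ Wishart(W1_k, W2_k)

with priors N(0,1) on the means, Wishart(3, I/3) on the precisions and a
symmetric Dirichlet on the weights.  Training minimizes the negative
Monte-Carlo evidence lower bound

    L = −( (1/L) Σ_l  mean_i log p(s_i | θ_l)  −  KL(q ‖ p) ),

where θ_l are reparameterized draws of (α, μ, Λ); gradients flow through
the draws into both the variational parameters (N1, N2, W1, W2, D) and the
attention block, by minibatch SGD on a small built-in reverse-mode tape.
Posterior responsibilities p(z|s) partition feature space into
normal / transition / falling regions; renders of the mixture likelihood and
the region partition (probabilistic maps) are first-class outputs.

Because no public data accompany the protocol, the package ships a
synthetic session generator (walk → ~30 s in-place spin → fall onto a
mattress, 60 FPS, two camera heights of 1.6 m and 3.1 m, detector jitter)
that produces labeled bounding-box streams for training and evaluation.

## Worked example

```python
from fallwatch import (FallDetector, FitConfig, SessionSpec, evaluate_detector,
                       simulate_cohort, simulate_session)

cohort = simulate_cohort(n_subjects=15, seed=7)           # 30 labeled streams
detector = FallDetector.train(cohort[:20], FitConfig(K=3), seed=0)
print("cluster regions:", detector.cluster_tags)

report = evaluate_detector(detector, cohort[20:])
print(f"held-out window accuracy: {report['label_accuracy']:.3f} "
      f"over {report['n_windows']} windows")

fall = simulate_session(SessionSpec(walk_s=5, spin_s=10, seed=99))
for e in detector.alarm_events(fall.bboxes):
    print(f"{e.state} at t={e.t_enter:.2f} s (impact at {fall.impact_time:.2f} s)")
```

Output:

```
cluster regions: {0: 'normal', 1: 'transition', 2: 'falling'}
held-out window accuracy: 0.995 over 27220 windows
warning1 at t=14.93 s (impact at 15.70 s)
warning2 at t=15.65 s (impact at 15.70 s)
```

The three mixture components are tagged by majority vote of labeled
training windows.  On the held-out subjects, 99.5% of 21-frame windows
classify to the correct posture region.  On a new fall session the
transition alarm fires 0.77 s before the impact — the same order as the
~0.67 s that 40 consecutive centroid samples span at 60 FPS — and the
falling alarm fires while the body is still settling onto the mattress.

The same pipeline is available from a shell:

```bash
fallwatch simulate --n-subjects 15 --seed 7 --out data/
fallwatch fit      --data data/ --seed 0 --out model/
fallwatch map      --model model/model.json --out maps/ --png
fallwatch alarm    --model model/model.json --stream data/subject00_cam1.6.bboxes.csv --out alarm.csv
echo $?            # 0 = normal, 1 = warning1 reached, 2 = warning2 reached
```

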