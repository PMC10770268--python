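# surgflow

Execution, situation recognition, and control of **surgical process models**
in BPMN 2.0 and CMMN 1.1 — a self-contained engine for workflow-driven
situation awareness in the operating room.

## The problem

Intraoperative assistance systems need to know *what is happening right
now*: which surgical step is being performed, which steps can plausibly
come next, and how much of the intervention remains.  A formal surgical
process model (SPM) supplies that process knowledge, but a single notation
rarely fits a whole intervention.  A structured process language (BPMN)
states the course explicitly — every step, decision, and join — yet it
turns variable or optional work into gateway workarounds; a case language
(CMMN) expresses weakly structured work naturally — items become startable
when their entry criteria fire, optional items are simply not required —
but it cannot forbid everything the stricter model would.

`surgflow` implements the whole loop for both notations and their
combinations, for people building or studying situation-recognition
systems (SRS) on top of workflow engines:

* **model_io** — read/write/validate a vendor-free subset of BPMN 2.0 and
  CMMN 1.1 XML (phases as sub-processes/stages, steps as user/human tasks,
  variable order as parallel-gateway blocks / sentry-free siblings,
  optional steps as XOR bypasses / `required=false` + manual activation).
* **bpmn** — token execution: parallel gateways activate all branches,
  exclusive decisions resolve implicitly by the first completed task, and a
  `camunda_compat` switch reproduces the reference engine's auto-skip of
  optional tasks once a sibling branch completes.
* **cmmn** — plan-item lifecycle (`available → enabled/active → completed`,
  `disabled` for skipped optionals), sentries on the *complete* event,
  manual stage/case completion when optional items block auto-completion.
* **recognition** — fuse sensor evidence with process knowledge:

  `P(step) ∝ w·p_sensor(step) + (1−w)·q(step)`

  where `p_sensor` comes from declarative situation rules (instrument sets,
  actor positions, or step labels), `q` is uniform over the model's next
  possible steps plus the current one, and the impact weight defaults to
  `w = 0.8` (80 % sensor, 20 % process knowledge).
* **knowledge** — next possible steps (static traversal or replay),
  completable running activities, reasonableness of a candidate situation,
  and the remaining surgery duration `RSD = Σ duration(required steps not
  yet done)` with `delay = clock − expected elapsed`.
* **control** — the situation loop: the best-scored candidate is started on
  the runtime, its predecessors are completed, stages and cases are closed
  and call activities advanced as needed; unreasonable candidates are
  refused without touching the runtime state.
* **fixtures** — synthetic model families for a nine-phase robot-assisted
  esophagectomy (RAMIE, instrument/position sensors) and a five-phase
  cochlea implantation (CI, step-label sensors), in all four variants
  (BPMN, CMMN, mixed and structured combination), plus deterministic valid
  and distorted observation streams.
* **oracle** — brute-force enumeration of every accepted complete trace,
  the independent check for both engines; a block of `k` required and `m`
  optional variable-order steps admits `Σ_j C(m,j)·(k+j)!` traces
  (5 steps with one optional: 4! + 5! = 144).

## Worked example

```bash
surgflow generate --spec ci --out out/ci --seed 7
surgflow run --models out/ci --variant cmmn --stream out/ci/streams/valid.jsonl
```

```
    time  recognized                               ok  actions
------------------------------------------------------------------------------
     0.0  s01_01_patient_positioning               yes -
     9.8  s01_02_sterile_draping                   yes complete_task:s01_01_patient_positioning
    18.9  s02_01_skin_incision                     yes complete_task:s01_02_sterile_draping
    29.5  s02_02_mastoidectomy                     yes complete_task:s02_01_skin_incision
    38.7  s02_03_posterior_tympanotomy             yes complete_task:s02_02_mastoidectomy
    48.9  s03_02_cochleostomy_drilling             yes complete_task:s02_03_posterior_tympanotomy; manual_start:s03_02_cochleostomy_drilling
    59.7  s03_03_electrode_insertion               yes -
    69.1  s04_01_electrode_testing                 yes complete_task:s03_02_cochleostomy_drilling; complete_task:s03_03_electrode_insertion; complete_stage:phase_03_operation_under_microscope
    78.3  s04_03_electrode_fixation                yes complete_task:s04_01_electrode_testing
    88.1  s05_01_wound_closure                     yes complete_task:s04_03_electrode_fixation; complete_stage:phase_04_operation_after_microscope
    97.6  s05_02_bandage_application               yes complete_task:s05_01_wound_closure
------------------------------------------------------------------------------
session complete; 0 refusal(s); 11 steps completed
RSD 0 min, delay -12 min
```

Each row is one simulated observation: the recognized step (here the
cochleostomy route was taken, so the implant-dependent alternative never
appears), whether it was judged reasonable, and the control actions issued
— task completions for ended situations, a `manual_start` for the optional
drilling step, and explicit `complete_stage` calls where un-run optional
items block automatic stage completion.  The session ends complete with no
refusals; RSD 0 means every modeled required step was performed, and the
negative delay says the simulated run was 12 minutes faster than the
modeled durations.  Running the same stream with `--variant bpmn` or
`--variant structured` completes the identical step trace; a distorted
stream (e.g. `streams/skip_required.jsonl`) ends incomplete with refusal
rows instead.

```bash
surgflow enumerate --model out/ci/ci.bpmn
# 6 complete trace(s)
```

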