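# Methods

This note documents the semantics the package implements, the parameters
that matter, what the synthetic fixtures do and do not emulate, and the
design decisions taken where more than one reading was defensible.

## Model subset and dialect

Both readers accept a deliberate subset of the OMG notations — the elements
needed to transfer surgical process information, nothing more:

| process information | BPMN | CMMN |
|---|---|---|
| phases and steps | sub-process containing user tasks | stage containing human tasks |
| order / dependency | sequence flow | sentry (entry criterion on the *complete* event) |
| variable step order | parallel (AND) gateway block | siblings without mutual sentries |
| optional step | XOR gateway bypass | no required rule + manual activation rule |
| different procedures | XOR gateway branches | optional siblings (see limitations) |
| foreseen events | signal boundary event | event listener |
| notation bridge | call activity → case | — |

Everything else is rejected with the offending element names; nothing is
silently dropped.  The dialect is vendor-free: plain OMG namespaces, rule
expressions restricted to literal `true`/`false` (rules are markers here,
not expressions), and one documented extension element
`{urn:surgflow:extension}expectedDuration` holding a step's expected
duration in minutes.  Diagram-interchange sections are ignored on read and
never written.  Event elements parse and round-trip but have no runtime
semantics in this version; event-driven behavior is out of scope.

Models are assumed **block-structured**: every gateway split has a matching
join of the same kind and blocks nest properly.  The engines, the duration
estimate, and the trace oracle all rely on the region tree this induces
(sequence / AND block / XOR block / sub-process body).  Optionality in BPMN
is recognized structurally: a two-branch XOR whose one branch is empty and
whose other holds a single task marks that task optional.

## Execution semantics

**BPMN (token engine).**  Tokens advance from the start event until they
rest on user tasks.  AND splits activate every branch; XOR splits register
a *pending decision* — no conditions are evaluated, completing the first
task of a branch selects it and bypasses the tasks of the other branches.
Completing a task that is neither active nor activatable is an
out-of-order error; re-completing one is a regression error.  Sub-processes
complete automatically at their end event.  A `camunda_compat` switch
(default **on**) reproduces an engine peculiarity that shapes runtime
behavior for optional steps inside AND blocks: once a task on a sibling
branch completes, an undecided XOR guarding an optional resolves to its
bypass, and the optional can no longer be executed (a *late optional*
refusal).  With the switch off the optional stays activatable until the
join.  Only one completion happens per engine call; true concurrency is not
modeled (variable-order steps are semi-parallel, performed one at a time).

**CMMN (lifecycle engine).**  Plan items move through
`available → enabled/active → completed`, with `disabled` for optional
items skipped at stage closure.  An item leaves `available` when its
containing stage is active and its entry criteria are satisfied (all
on-parts completed); required items activate automatically, optional items
become `enabled` and need a manual start.  A stage with only required
children auto-completes on the last completion; a stage with optional
children must be completed explicitly by the controlling system, which
disables its un-run optionals — deliberately the engine behavior this
models, not the stricter OMG autocomplete attribute.  The case itself is
completed and closed explicitly after the last task; a closed case is
immutable.  Discretionary tasks are not implemented; optionality is
encoded through the rule pair above.

The case variant is by construction more permissive than the process
variant: its accepted trace set is a superset, and the difference consists
exactly of (a) optional steps executed after their block was already left
(within the same stage) and (b) several — or zero — branches of an
"exclusive" choice, which a case model can only express as optional
siblings.  Both classes are verified by the test suite and surface in the
session matrix as streams refused on BPMN but accepted on CMMN.

## Situation recognition and fusion

An observation carries instruments in use, actor positions, or directly a
step label.  Declarative situation rules map sensor signatures to steps;
every firing rule adds its base score to its target, a step label scores
its named step 1.0, and the result is normalized.  Sensor and process
knowledge are then blended as a convex combination

```
fused(c) = w · p_sensor(c) + (1 − w) · q(c)
```

with `q` uniform over the next possible steps plus the current one, and
renormalized.  The figure-style default is `w = 0.8`.  This formula is this
package's definition of the knowledge combination — the configurable
*impact* value determines how strongly process knowledge can override the
sensors.  Ties break on the lexically smallest step id so logs are
reproducible.  Process knowledge does not veto candidates inside the
fusion; reasonableness is judged separately by the controller.
Activity-level recognition shares the step mechanism with a finer label
set; no separate algorithm exists.

Process knowledge defaults to the BPMN variant of the intervention even
when a case or combination model is controlled, since the sequence-flow
structure states the expected course most explicitly.  When the executed
course diverges from what the structured variant accepts (exactly the
case-model flexibility classes above), the knowledge source falls back to
the controlled runtime automatically; a configuration flag
(`knowledge_source: runtime`) selects the runtime source outright.

## Control loop

An observation marks the *start* of a situation.  The controller, never the
engines, owns tolerance policy:

1. repetition — the candidate equals a still-running started step — is a
   no-op;
2. a candidate already completed is a regression and is refused;
3. otherwise the candidate is secured on a **copy** of the runtime:
   resolve the exclusive decision its token needs (BPMN) or manually start
   it if enabled (CMMN); a start that would bypass a previously started
   step is not allowed to steal the decision — the second exclusive path
   must be refused, not silently selected;
4. previously started steps are completed in observation order (the
   matching running tasks, so the next tasks activate), followed by the
   bookkeeping the notation needs: manual stage completion, case
   complete/close, advancing the root process over call activities;
5. on success the copy replaces the runtime; on any engine error the copy
   is discarded — a refusal row never leaves partial state changes.

Candidates in the first stage of a case bypass the reasonableness veto
(configurable, default on), reflecting the shallower plausibility checking
of case control; in a combination model this applies only when the
intervention actually starts in a case.  At end of stream the remaining
started steps are completed and stages/cases closed where their required
items allow; a session after a skipped required step therefore ends
incomplete, with the refusals on record.

## Synthetic fixtures

Two intervention families define the test conditions.  **RAMIE** has nine
phases and 24 steps with two variable-order groups (one containing an
optional member), standalone optionals, and an exclusive choice of
anastomosis technique; its streams simulate instrument sets and a surgeon
position per step, with one rule per step drawn deterministically from the
vocabularies (unique instrument pairs, so adjacent steps are
distinguishable).  **CI** has the five phases preparation, access,
operation under and after the microscope, and follow-up — 13 steps, more
linear, with an implant-dependent exclusive insertion route; its streams
carry the step name directly.  Phase and step names are clinically
plausible placeholders; step counts per phase are configurable defaults.
Every step's expected duration defaults to 10 minutes so RSD arithmetic is
legible in logs.

Streams are sampled with a seeded generator (observation times accumulate
the modeled durations with ±10 % jitter; identical seeds give byte-identical
files).  A valid stream replays one accepted order; each distortion kind
injects exactly one anomaly class: skipping a required or an optional step,
regressing to a step from an earlier phase, repeating an observation,
executing a second exclusive path, or delaying an optional past its block.

What the generator does **not** emulate: real sensor noise (rules always
fire exactly), ambiguous or missing observations, concurrent true
parallelism, event occurrences (bleeding etc.), or clinically validated
step content.  Passing tests therefore demonstrate the engine, fusion, and
control semantics under clean evidence — not recognition robustness on
real OR data.

## Numerical and procedural choices

* Reasonableness of a candidate = it is activatable after the replayed
  trace, or one modeled step ahead of a running activity, or a repetition
  of the current step.  The one-step-ahead clause is what lets the
  controller complete the matching running task.
* RSD sums required, not-yet-done steps only; parallel branches add, and
  exclusive blocks contribute their maximum-duration branch until the trace
  commits to one — a conservative upper estimate.  Missing durations make
  the estimate *unavailable* (a `None` result), never an exception.
* Next-step lookahead depth is 1 by default (a `depth` parameter exists).
* Trace enumeration caps at 10 000 traces (`truncated` flag); counting uses
  the closed form / multinomial convolution on the region tree instead of
  materializing traces.
* All randomness (rules, streams) flows from explicit integer seeds.

## Known limitations

* Only the `complete` sentry event, no if-part conditions, repetition
  rules, milestones, or case file items; no timers, message flows, or
  multi-instance activities; boundary events and event listeners are
  parse-only.
* Non-block-structured BPMN parses but cannot be executed or enumerated.
* The case engine intentionally reproduces the false-positive classes of
  the optional-sibling modeling; a stricter case style (more stages, more
  sentries) would narrow them at the cost of flexibility.
* Learning next-step probabilities from recorded past cases is out of
  scope; the process prior is uniform.
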