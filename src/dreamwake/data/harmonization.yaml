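# Canonical vocabulary for study context factors and participant-record
# stages.  Keys are lower-cased free-text labels as they appear in source
# tables; values are the canonical factor levels used throughout the
# package.  Unmapped non-blank labels are an error, never silently "other".
method:
  alarm: alarm
  buzzer: alarm
  sound: alarm
  tone: alarm
  beep: alarm
  name: name
  calling: name
  call: name
  knock: other
  question: other
  enter: other
  experimenter: other
  other: other
question:
  mind: mind
  thoughts: mind
  dream: dream
  dreaming: dream
  other: other
repeated:
  repeated: repeated
  multiple: repeated
  single: single
  both: both
setting:
  lab: laboratory
  laboratory: laboratory
  home: home
  both: both
sleep_type:
  night: night
  nap: nap
days:
  ">1": multiple
  multiple: multiple
  "1": single
  single: single
gentle:
  "yes": "yes"
  gentle: "yes"
  "no": "no"
stage:
  n1: N1
  s1: N1
  stage 1: N1
  n2: N2
  s2: N2
  stage 2: N2
  n3: N3
  s3: N3
  s4: N3
  sws: N3
  stage 3: N3
  stage 4: N3
  nrem: NREM
  rem: REM
  r: REM
  w: W
  wake: W
  unknown: unknown
  "#n/a": unknown
report:
  with_recall: with_recall
  experience with recall: with_recall
  de: with_recall
  without_recall: without_recall
  experience without recall: without_recall
  white dream: without_recall
  dwr: without_recall
  no_report: no_report
  no report: no_report
  null report: no_report
  ne: no_report
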