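# FFQ category -> quantitative frequency conversion, version 1.
#
# "frequency" items carry the six-level touchscreen response scale used for
# meat, fish and cheese items (times/week).  "alcohol" has its own
# seven-level scale (times/week).  Quantitative items (fruit pieces/day,
# vegetable tablespoons/day, coffee/tea cups/day) are entered numerically
# and need no conversion.  Users may override this file to audit or adapt
# the mapping.
version: 1
classes:
  frequency:
    unit: times/week
    responses:
      "never": 0.0
      "less than once a week": 0.5
      "once a week": 1.0
      "2-4 times a week": 3.0
      "5-6 times a week": 5.5
      "once or more daily": 7.0
  alcohol:
    unit: times/week
    responses:
      "never": 0.0
      "special occasions only": 0.125
      "one to three times a month": 0.5
      "one to two times a week": 1.5
      "three to four times a week": 3.5
      "five to six times a week": 5.5
      "daily or almost daily": 7.0
units:
  fresh_fruit: pieces/day
  dried_fruit: pieces/day
  cooked_vegetables: tablespoons/day
  raw_vegetables: tablespoons/day
  coffee: cups/day
  tea: cups/day
  milk: mL/day
missing_responses:
  - "do not know"
  - "prefer not to answer"
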