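name: flat
source: 'synthetic flat model: carrier = noncarrier, constant hazards (BC 0.02/yr,
  contralateral 0.02/yr, OV 0.01/yr); every likelihood ratio is exactly 1'
age_grid:
- 0.0
- 5.0
- 10.0
- 15.0
- 20.0
- 25.0
- 30.0
- 35.0
- 40.0
- 45.0
- 50.0
- 55.0
- 60.0
- 65.0
- 70.0
- 75.0
- 80.0
- 85.0
- 90.0
- 95.0
cumulative_risk:
  carrier:
    breast_first:
    - 0.0
    - 0.09516258196404048
    - 0.18126924692201818
    - 0.2591817793182821
    - 0.3296799539643607
    - 0.3934693402873666
    - 0.4511883639059736
    - 0.5034146962085906
    - 0.5506710358827784
    - 0.5934303402594009
    - 0.6321205588285577
    - 0.6671289163019205
    - 0.6988057880877979
    - 0.7274682069659875
    - 0.7534030360583935
    - 0.7768698398515702
    - 0.7981034820053446
    - 0.8173164759472653
    - 0.8347011117784134
    - 0.8504313807773649
    breast_contralateral:
    - 0.0
    - 0.09516258196404048
    - 0.18126924692201818
    - 0.2591817793182821
    - 0.3296799539643607
    - 0.3934693402873666
    - 0.4511883639059736
    - 0.5034146962085906
    - 0.5506710358827784
    - 0.5934303402594009
    - 0.6321205588285577
    - 0.6671289163019205
    - 0.6988057880877979
    - 0.7274682069659875
    - 0.7534030360583935
    - 0.7768698398515702
    - 0.7981034820053446
    - 0.8173164759472653
    - 0.8347011117784134
    - 0.8504313807773649
    ovarian:
    - 0.0
    - 0.048770575499285984
    - 0.09516258196404048
    - 0.1392920235749422
    - 0.18126924692201818
    - 0.22119921692859512
    - 0.2591817793182821
    - 0.29531191028128656
    - 0.3296799539643607
    - 0.36237184837822667
    - 0.3934693402873666
    - 0.42305018961951335
    - 0.4511883639059736
    - 0.47795422323898396
    - 0.5034146962085906
    - 0.5276334472589853
    - 0.5506710358827784
    - 0.5725850680512734
    - 0.5934303402594009
    - 0.6132589765454988
  noncarrier:
    breast_first:
    - 0.0
    - 0.09516258196404048
    - 0.18126924692201818
    - 0.2591817793182821
    - 0.3296799539643607
    - 0.3934693402873666
    - 0.4511883639059736
    - 0.5034146962085906
    - 0.5506710358827784
    - 0.5934303402594009
    - 0.6321205588285577
    - 0.6671289163019205
    - 0.6988057880877979
    - 0.7274682069659875
    - 0.7534030360583935
    - 0.7768698398515702
    - 0.7981034820053446
    - 0.8173164759472653
    - 0.8347011117784134
    - 0.8504313807773649
    breast_contralateral:
    - 0.0
    - 0.09516258196404048
    - 0.18126924692201818
    - 0.2591817793182821
    - 0.3296799539643607
    - 0.3934693402873666
    - 0.4511883639059736
    - 0.5034146962085906
    - 0.5506710358827784
    - 0.5934303402594009
    - 0.6321205588285577
    - 0.6671289163019205
    - 0.6988057880877979
    - 0.7274682069659875
    - 0.7534030360583935
    - 0.7768698398515702
    - 0.7981034820053446
    - 0.8173164759472653
    - 0.8347011117784134
    - 0.8504313807773649
    ovarian:
    - 0.0
    - 0.048770575499285984
    - 0.09516258196404048
    - 0.1392920235749422
    - 0.18126924692201818
    - 0.22119921692859512
    - 0.2591817793182821
    - 0.29531191028128656
    - 0.3296799539643607
    - 0.36237184837822667
    - 0.3934693402873666
    - 0.42305018961951335
    - 0.4511883639059736
    - 0.47795422323898396
    - 0.5034146962085906
    - 0.5276334472589853
    - 0.5506710358827784
    - 0.5725850680512734
    - 0.5934303402594009
    - 0.6132589765454988
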