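# Temporal Perceptual Aberration Scale (tPAS) statements.
# Ratings: 1 (not at all) .. 10 (very much).
1	I sometimes have the feeling that I have already been in a situation like the one I am currently in (deja vecu).
2	I sometimes re-imagine experiences I had in the past.
3	I dedicate much time to planning my schedule.
4	I sometimes have the feeling of having already seen things that are presented to me (deja vu).
5	I sometimes find myself dreaming awake.
6	I sometimes look upon myself from a future point of view.
7	I sometimes imagine myself as a younger child.
8	I sometimes have a dream in which I meet my past self.
9	I sometimes have a dream in which I meet my future self.
10	I sometimes think deeply about my old age.
11	I sometimes know what to do as I already predicted such a situation without previously experiencing it.
12	I sometimes feel that I am older than my current age.
13	I sometimes feel that I am younger than my current age.
14	I sometimes have the feeling that I know what is going to happen.
15	I sometimes regret key decisions I took in my life.
16	I am sometimes bothered by key decisions I have to make in the far future.
17	I sometimes believe that patterns or situations that have already happened will re-occur again.
18	I am sometimes not sure if some events had really occurred to me or were just imagined.
19	I sometimes feel sure when performing an action, although I have never done it before.
20	I am sometimes not sure if I did something that I had already done.
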