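# cue phrase	hinted discourse label
possible	hypothesis
we hypothesized	hypothesis
may be	hypothesis
might	hypothesis
presumably	hypothesis
data not shown	result
we found	result
we observed	result
demonstrate	implication
suggest	implication
taken together	implication
these data indicate	implication
consistent with	implication
we conclude	implication
we sought to	goal
to determine whether	goal
to test	goal
to investigate	goal
we asked	goal
it is known	fact
has been shown	fact
well established	fact
were treated	method
was performed	method
were incubated	method
remains unclear	problem
poorly understood	problem
little is known	problem
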