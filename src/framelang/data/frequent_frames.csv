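pattern,pct
the OBJ,6.30
that is a OBJ,4.73
and the OBJ,4.31
a OBJ,4.10
it is a OBJ,3.78
this is a OBJ,3.57
and a OBJ,3.26
can you say OBJ,2.94
here is the OBJ,2.63
and OBJ,2.42
where is the OBJ,1.89
that is the OBJ,1.79
look at the OBJ,1.79
i have the OBJ,1.47
you want the OBJ,1.16
color is the OBJ,1.16
is that the OBJ,1.16
there is the OBJ,1.05
you put the OBJ,1.05
to put the OBJ,0.95
one is the OBJ,0.95
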