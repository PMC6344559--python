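subject_id,episode_id,age_years,sex,location,platelet_k_mcl,anc_k_mcl,chemo_7d,radiation_7d,sot,bmt,immunosupp_7d,culture_time,sample_time,il8,ccl3,hspa1b,gzmb,mmp8,crystalloid_ml_24h,weight_kg,icu_transfer_72h,resp_support_72h,vasoactive_72h,ams_72h,death_72h,infected,death_28d
S0001,E1,11.1589,F,ward,2866.37,0.108,1,1,0,0,0,2016-08-06T14:45:39,2016-08-06T17:34:26,293.473,8.425,2189.32,8.61,40839.02,424.6,36.28,0,0,0,0,0,0,0
S0001,E2,11.1589,F,ward,169.11,0.108,1,1,0,0,0,2016-09-12T01:16:23,2016-09-12T02:49:57,100.973,90.314,724.444,3.343,13881.472,544.9,36.28,0,0,0,0,0,0,0
S0001,E3,11.1589,F,ward,130.25,0.108,1,1,0,0,0,2016-12-07T09:39:46,2016-12-07T12:08:41,4231.683,13.827,662.264,90.773,1004.722,805.6,36.28,0,0,0,0,0,0,0
S0002,E1,5.8514,F,ward,319.48,1.803,1,0,0,1,1,2016-11-03T22:16:16,2016-11-03T21:51:46,282.678,88.782,3623.78,442.007,1081.614,297.3,14.74,0,0,0,0,0,0,0
S0003,E1,7.6629,M,ward,87.72,0.989,1,0,1,0,0,2017-03-21T00:23:11,2017-03-20T23:08:42,48.707,24.685,851.084,57.57,614.211,523.5,22.7,0,0,0,0,0,0,0
S0004,E1,3.7152,F,ward,699.34,0.206,0,0,0,1,1,2017-01-16T08:19:26,2017-01-16T09:11:07,96.831,154.643,364.088,12.171,329.089,264.1,12.75,0,0,0,0,0,0,0
S0004,E2,3.7152,F,ward,47.24,0.206,0,0,0,1,1,2017-02-21T21:27:03,2017-02-21T22:36:30,135.737,115.91,103488.939,76.91,23479.537,284.4,12.75,0,0,0,0,0,1,0
S0005,E1,2.6926,F,picu,253.24,1.191,1,1,0,0,0,2017-03-16T22:33:24,2017-03-16T19:41:52,307.567,59.478,350.263,15.828,1955.681,104.9,10.45,0,0,0,0,0,0,0
S0006,E1,7.0882,F,picu,87.65,2.263,1,0,0,0,0,2017-04-11T02:51:24,2017-04-11T01:43:15,1375.195,58.735,9240.193,12.286,764.991,491.4,21.13,0,0,0,0,0,1,0
S0007,E1,8.7291,M,ward,768.22,1.987,0,0,1,0,1,2017-07-27T17:06:31,2017-07-27T17:54:10,240.125,87.443,474.077,16.678,943.346,668.1,23.64,0,0,0,0,0,1,0
S0008,E1,19.7533,M,ward,9.55,5.709,1,0,0,0,0,2017-06-01T05:28:18,2017-06-01T04:06:58,7717.047,80.849,552.553,5.79,10920.854,837.1,55.35,0,0,1,0,0,0,1
S0008,E2,19.7533,M,picu,208.06,5.709,1,0,0,0,0,2017-07-07T13:19:13,2017-07-07T15:20:07,3128.469,9.861,326.925,13.569,635.23,263.4,55.35,0,0,0,0,0,1,0
S0008,E3,19.7533,M,ward,877.04,5.709,1,0,0,0,0,2017-07-18T15:21:02,2017-07-18T13:45:08,37.352,70.414,15129.994,7.641,3346.644,789.2,55.35,0,0,0,0,0,1,0
S0009,E1,16.5955,M,ward,80.89,0.782,1,0,0,0,0,2016-09-28T14:30:59,2016-09-28T15:33:49,614.361,141.943,2091.132,36.426,444.586,520.1,41.18,0,0,0,0,0,0,0
S0009,E2,16.5955,M,ward,104.82,0.782,1,0,0,0,0,2016-11-27T22:59:37,2016-11-27T22:31:33,199.79,8.435,776.477,7.849,1054.879,830.4,41.18,0,0,0,0,0,0,0
S0010,E1,4.7604,M,ward,1056.07,0.367,0,0,0,0,0,2017-03-21T03:14:57,2017-03-21T01:06:16,415.552,7.49,754.838,6.338,355.106,229,12.52,0,0,0,0,0,0,0
S0011,E1,3.9222,M,picu,250.99,0.273,1,0,0,1,1,2017-04-18T09:48:31,2017-04-18T09:04:37,212.722,22.975,2488.179,18.266,5526.719,33.5,12,0,0,1,0,0,1,1
S0012,E1,3.3441,F,ward,104.39,0.726,1,1,1,0,1,2017-05-09T09:56:27,2017-05-09T09:41:12,2414.113,112.241,608.082,29.229,18280.492,173.7,9.25,0,0,1,0,0,1,1
S0012,E2,3.3441,F,ward,115.04,0.726,1,1,1,0,1,2017-06-17T03:13:44,2017-06-17T05:04:56,4371.657,228.176,1633.876,33.811,2466.029,59.7,9.25,0,0,0,0,0,0,0
S0013,E1,15.0903,F,ward,169.52,0.279,1,0,0,1,1,2017-03-19T04:42:14,2017-03-19T04:27:01,444.898,13.533,3280.783,6.157,858.29,768.5,36.67,0,0,0,0,0,0,0
S0014,E1,8.0142,F,ward,138.9,0.993,1,0,0,0,0,2017-06-26T00:24:54,2017-06-26T03:07:08,304.957,4.586,550.111,6.605,1305.814,542.5,21.28,0,0,0,0,0,0,0
S0015,E1,2.1247,M,ward,11.41,4.218,1,0,0,1,0,2016-09-20T02:37:43,2016-09-20T03:33:24,35.49,6.786,576.312,5.987,2102.638,193,9.93,0,0,0,0,0,0,0
S0016,E1,36.8063,F,ward,117.56,2.135,1,0,0,1,1,2016-07-23T03:00:27,2016-07-23T02:23:17,240.077,126.65,2371.699,10.808,8137.909,1380.3,47.25,0,0,0,0,0,0,0
S0016,E2,36.8063,F,ward,621.89,2.135,1,0,0,1,1,2016-08-29T14:33:57,2016-08-29T16:23:24,243.722,18.579,7399.186,22.043,679.015,898.6,47.25,0,0,0,0,0,0,0
S0017,E1,9.8106,M,picu,29.76,0.061,0,0,1,0,1,2017-02-01T21:41:33,2017-02-01T21:58:26,43.887,205.875,3690.411,23.692,8168.466,362.4,26.29,0,0,0,1,0,1,1
S0018,E1,5.1661,F,ward,69.58,0.67,1,0,1,0,1,2016-09-27T12:57:01,2016-09-27T11:41:52,30.753,2.585,506.758,86.166,5104.363,95.5,14.99,0,0,0,0,0,0,0
S0019,E1,29.9324,M,ward,30.57,0.491,0,0,0,1,1,2016-12-01T17:11:54,2016-12-01T17:55:05,1701.919,38.872,4085.646,136.358,22783.944,3763,41.01,0,0,0,0,0,1,0
S0020,E1,14.6111,F,ward,41.21,0.754,1,0,0,0,0,2016-12-11T12:14:06,2016-12-11T11:25:00,455.933,12.188,900.606,72.978,4364.244,856.7,44.04,0,0,0,0,0,0,0
S0020,E2,14.6111,F,ward,126,0.754,1,0,0,0,0,2017-01-13T07:37:53,2017-01-13T09:22:01,85.904,13.684,1370.515,14.291,202.496,377,44.04,0,0,0,0,0,0,0
S0021,E1,38,F,ward,16.89,0.289,0,0,0,0,0,2016-09-10T23:28:11,2016-09-10T21:25:54,909.668,5.838,181.169,30.921,13620.003,15.5,54.2,0,0,0,0,0,1,0
S0022,E1,7.9107,M,ward,197.01,1.26,1,0,0,0,0,2017-04-12T15:03:10,2017-04-12T14:41:27,476.33,37.537,2314.727,15.946,15123.683,192.1,23.17,0,0,0,0,0,0,0
S0023,E1,5.9028,M,ward,147.49,0.07,1,0,0,1,1,2017-03-11T11:15:40,2017-03-11T13:10:36,199.989,4.171,2918.926,19.387,1801.237,390.8,16.39,0,0,0,0,0,0,0
S0024,E1,34.2706,F,cicu,216.7,0.934,0,0,0,1,1,2016-12-19T10:41:56,2016-12-19T07:47:21,106.468,62.231,1343.005,5.855,10154.683,540.6,51.77,0,0,0,0,0,0,0
S0025,E1,4.1092,F,ward,149.92,0.4,1,0,0,1,1,2017-01-27T01:53:44,2017-01-26T23:01:38,26.195,15.954,3025.122,115.065,6888.085,72.6,12.17,0,0,0,0,0,0,0
S0026,E1,6.8654,M,ward,41.28,3.05,1,0,0,0,0,2017-05-16T03:20:45,2017-05-16T05:44:36,68.006,15.753,1192.569,6.753,304.029,513,19.47,0,0,0,0,0,0,0
S0027,E1,5.1132,M,ward,591.7,2.274,1,0,0,0,0,2017-02-22T00:18:06,2017-02-21T23:10:55,66.057,22.288,2502.398,11.179,12413.669,392.7,15.42,0,0,0,0,0,0,0
S0028,E1,13.051,F,ward,101.32,4.489,0,0,1,0,1,2016-10-04T14:53:19,2016-10-04T16:03:35,33.912,101.55,2716.397,15.727,367.36,345.7,30.22,0,0,0,0,1,0,1
S0028,E2,13.051,F,ward,31.68,4.489,0,0,1,0,1,2016-10-24T05:32:37,2016-10-24T08:15:22,352.746,159.813,3137.724,8.059,578.282,514.2,30.22,0,0,0,0,0,0,0
S0029,E1,16.8646,M,picu,649.42,0.05,0,0,0,0,0,2016-10-05T09:24:39,2016-10-05T09:15:21,2157.115,386.217,6242.454,5.451,28307.62,275.7,44.81,0,1,0,0,0,0,0
S0030,E1,19.5148,M,ward,69.12,2.41,0,0,0,1,1,2016-11-01T06:56:22,2016-11-01T08:41:24,1277.077,18.176,2631.349,8.949,22287.956,1278.6,43.05,0,0,0,0,0,0,0
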